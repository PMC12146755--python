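"""Coarse-grained SAXS: Debye profiles, Guinier, Kratky, chi, multistate fit.

The scattering engine is a uniform-form-factor Debye sum over beads (one
bead per residue, or every atom with uniform weight). It deliberately
omits atomic form factors, excluded volume and the hydration layer: the
package's claims are comparative — rigid vs flexible ensembles, mixture
recovery — not absolute-intensity parity with full atomistic predictors.

The multistate selection stage enumerates all small subsets of a candidate
profile pool and fits nonnegative weights plus a global scale against an
experimental curve, reporting the best subset for each ensemble size N and
the overall best by chi.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

from .ensemble_io import StructureState, _normalize_weights
from .errors import (
    ConvergenceError,
    FitError,
    ResolutionError,
    SizeError,
    ValidationError,
)

__all__ = [
    "SAXSProfile",
    "KratkyCurve",
    "GuinierResult",
    "EnsembleFitResult",
    "debye_profile",
    "ensemble_profile",
    "guinier_fit",
    "dimensionless_kratky",
    "chi_fit",
    "prune_pool",
    "select_multistate",
]


@dataclass
class SAXSProfile:
    """Scattering intensity vs momentum transfer q (1/A), with uncertainties."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.ndim != 1 or self.intensity.shape != self.q.shape:
            raise ValidationError("q and intensity must be matching 1-D arrays")
        if self.q.size < 5:
            raise ValidationError("profile needs at least 5 points")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValidationError("q must be positive and strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValidationError("sigma must match q in length")
            if np.any(self.sigma <= 0):
                raise ValidationError("sigma must be positive")

    def __len__(self) -> int:
        return self.q.size


@dataclass
class KratkyCurve:
    """Dimensionless Kratky transform: x = q*Rg, y = (q*Rg)^2 I(q)/I(0)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValidationError("x and y must match in length")

    def peak(self) -> tuple[float, float]:
        """Grid position and height of the curve maximum."""
        i = int(np.argmax(self.y))
        return float(self.x[i]), float(self.y[i])


def debye_profile(
    state: StructureState, q_grid: np.ndarray, bead_scheme: str = "calpha"
) -> SAXSProfile:
    """Debye-formula profile of one conformation with uniform form factors.

    I(q) = sum_ij f_i f_j sin(q d_ij)/(q d_ij), f = 1, sinc(0) := 1, so
    I(0) = n_beads^2 and the curve is reported on the supplied q grid.

    bead_scheme: ``"calpha"`` uses CA atoms (one bead per residue);
    ``"all-atom"`` uses every atom.
    """
    q = np.asarray(q_grid, dtype=float)
    if bead_scheme == "calpha":
        idx = np.flatnonzero(state.atom_names == "CA")
        if idx.size == 0:
            raise ResolutionError(f"no CA beads in state {state.label!r}")
        beads = state.coords[idx]
    elif bead_scheme == "all-atom":
        beads = state.coords
    else:
        raise ValidationError(f"unknown bead scheme {bead_scheme!r}")
    n = beads.shape[0]
    intensity = np.full(q.shape, float(n))
    if n > 1:
        d = pdist(beads)
        # sin(qd)/(qd) = sinc(qd/pi); pairs counted twice in the double sum.
        # chunk over q to bound the (n_q, n_pairs) scratch array
        chunk = max(1, int(2e7 // max(d.size, 1)))
        for lo in range(0, q.size, chunk):
            qs = q[lo:lo + chunk]
            intensity[lo:lo + chunk] += 2.0 * np.sinc(np.outer(qs, d) / np.pi).sum(axis=1)
    return SAXSProfile(q=q, intensity=intensity)


def ensemble_profile(profiles: list[SAXSProfile], weights) -> SAXSProfile:
    """Pointwise weighted sum of intensities over one shared q grid."""
    if not profiles:
        raise ValidationError("no profiles")
    w = _normalize_weights(weights)
    if len(w) != len(profiles):
        raise ValidationError("one weight per profile required")
    q = profiles[0].q
    for p in profiles[1:]:
        if p.q.shape != q.shape or not np.allclose(p.q, q, rtol=0, atol=0):
            raise ValidationError("profiles must share an identical q grid")
    intensity = np.einsum("i,ij->j", w, np.array([p.intensity for p in profiles]))
    return SAXSProfile(q=q, intensity=intensity)


@dataclass
class GuinierResult:
    rg: float  # Angstrom
    i0: float
    window: tuple[int, int]  # half-open index range of the final fit window
    n_iterations: int
    residual_rms: float


def guinier_fit(profile: SAXSProfile, qrg_max: float = 1.3, max_iter: int = 50) -> GuinierResult:
    """Iteratively windowed Guinier fit: ln I linear in q^2 at low q.

    Starting from the full curve, fit ln I = ln I0 - q^2 Rg^2 / 3, then
    shrink the window to q*Rg <= qrg_max and refit until the window is
    stable. Raises :class:`FitError` on a non-decaying low-q region and
    :class:`ConvergenceError` when the window drops below 5 points.
    """
    if np.any(profile.intensity <= 0):
        raise ValidationError("Guinier fit requires positive intensities")
    q2 = profile.q**2
    logi = np.log(profile.intensity)
    hi = len(profile)
    seen: set[int] = set()
    for iteration in range(1, max_iter + 1):
        if hi < 5:
            raise ConvergenceError("Guinier window shrank below 5 points")
        slope, intercept = np.polyfit(q2[:hi], logi[:hi], 1)
        if slope >= 0:
            raise FitError("non-decaying low-q region: Guinier slope >= 0")
        rg = float(np.sqrt(-3.0 * slope))
        new_hi = int(np.searchsorted(profile.q, qrg_max / rg, side="right"))
        new_hi = min(new_hi, len(profile))
        if new_hi == hi:
            resid = logi[:hi] - (slope * q2[:hi] + intercept)
            return GuinierResult(
                rg=rg,
                i0=float(np.exp(intercept)),
                window=(0, hi),
                n_iterations=iteration,
                residual_rms=float(np.sqrt(np.mean(resid**2))),
            )
        if new_hi < 5:
            raise ConvergenceError("Guinier window shrank below 5 points")
        seen.add(hi)
        if new_hi in seen:
            # window oscillates between two sizes; settle on the tighter one
            hi = min(hi, new_hi)
            slope, intercept = np.polyfit(q2[:hi], logi[:hi], 1)
            if slope >= 0:
                raise FitError("non-decaying low-q region: Guinier slope >= 0")
            rg = float(np.sqrt(-3.0 * slope))
            resid = logi[:hi] - (slope * q2[:hi] + intercept)
            return GuinierResult(
                rg=rg,
                i0=float(np.exp(intercept)),
                window=(0, hi),
                n_iterations=iteration,
                residual_rms=float(np.sqrt(np.mean(resid**2))),
            )
        hi = new_hi
    raise ConvergenceError(f"Guinier window did not stabilize in {max_iter} iterations")


def dimensionless_kratky(profile: SAXSProfile, rg: float, i0: float) -> KratkyCurve:
    """Dimensionless Kratky curve from a profile and its Guinier parameters.

    Globular particles peak near (sqrt(3), 3/e); extended or flexible ones
    show elevated amplitude at larger q*Rg.
    """
    if rg <= 0 or i0 <= 0:
        raise ValidationError("Rg and I0 must be positive")
    x = profile.q * rg
    y = x**2 * profile.intensity / i0
    return KratkyCurve(x=x, y=y)


def _interp_model(model: SAXSProfile, experiment: SAXSProfile):
    """Model intensity on the experiment grid, restricted to the overlap."""
    lo, hi = model.q[0], model.q[-1]
    inside = (experiment.q >= lo) & (experiment.q <= hi)
    if inside.sum() < 5:
        raise ValidationError("model and experiment q ranges barely overlap (<5 points)")
    qe = experiment.q[inside]
    return np.interp(qe, model.q, model.intensity), inside


def chi_fit(model: SAXSProfile, experiment: SAXSProfile) -> tuple[float, float]:
    """Reduced chi between a model curve and an experimental curve.

    The model is linearly interpolated onto the experimental grid where the
    ranges overlap; the scale c minimizing sum[(I_e - c I_m)^2 / sigma^2]
    has the closed form c = sum(I_e I_m / s^2)/sum(I_m^2 / s^2), and
    chi = sqrt( mean[(I_e - c I_m)^2 / sigma^2] ).
    """
    if experiment.sigma is None:
        raise ValidationError("experimental profile must carry uncertainties")
    im, inside = _interp_model(model, experiment)
    ie = experiment.intensity[inside]
    s = experiment.sigma[inside]
    denom = np.sum(im**2 / s**2)
    if denom <= 0:
        raise FitError("model intensity vanishes on the fit range")
    scale = float(np.sum(ie * im / s**2) / denom)
    chi = float(np.sqrt(np.mean(((ie - scale * im) / s) ** 2)))
    return chi, scale


def prune_pool(
    pool: list[tuple[str, SAXSProfile]],
    max_size: int = 10,
    sigma_fraction: float = 0.03,
) -> list[tuple[str, SAXSProfile]]:
    """Greedy max-min pruning of a candidate pool by pairwise chi distinctness.

    Subset selection is only well-posed when pool members are mutually
    distinguishable at the experimental noise level; near-duplicate curves
    make the fit degenerate. Starting from the lexicographically first
    label, candidates are added one at a time, each maximizing its minimum
    chi distance (at ``sigma_fraction`` relative uncertainty) to the
    profiles already kept. Returns at most ``max_size`` entries in label
    order.
    """
    if len(pool) <= 1:
        return list(pool)
    ordered = sorted(pool, key=lambda item: item[0])

    def pair_chi(a: SAXSProfile, b: SAXSProfile) -> float:
        pseudo = SAXSProfile(b.q, b.intensity, sigma_fraction * b.intensity)
        return chi_fit(a, pseudo)[0]

    chosen = [0]
    while len(chosen) < min(max_size, len(ordered)):
        best = None
        for j in range(len(ordered)):
            if j in chosen:
                continue
            dmin = min(pair_chi(ordered[j][1], ordered[k][1]) for k in chosen)
            if best is None or dmin > best[0]:
                best = (dmin, j)
        chosen.append(best[1])
    return [ordered[j] for j in sorted(chosen)]


@dataclass
class EnsembleFitResult:
    """Best multistate fits of an experimental curve from a candidate pool."""

    labels: tuple[str, ...]  # overall best subset
    weights: np.ndarray  # nonnegative, sum 1, aligned with labels
    chi: float
    scale: float
    per_n: dict[int, dict] = field(default_factory=dict)  # N -> best fit summary


def _fit_subset(profiles, experiment):
    """Nonnegative coefficients a_k minimizing ||(I_e - sum a_k I_k)/sigma||.

    The global scale and the normalized weights are both recovered from the
    coefficients (scale = sum a, weights = a / sum a), which makes the
    joint weights+scale problem a single NNLS solve.
    """
    interp = []
    inside_ref = None
    for p in profiles:
        im, inside = _interp_model(p, experiment)
        if inside_ref is None:
            inside_ref = inside
        elif not np.array_equal(inside, inside_ref):
            raise ValidationError("pool profiles cover different parts of the experiment")
        interp.append(im)
    ie = experiment.intensity[inside_ref]
    s = experiment.sigma[inside_ref]
    A = (np.array(interp) / s).T
    b = ie / s
    coef, _ = nnls(A, b)
    resid = b - A @ coef
    chi = float(np.sqrt(np.mean(resid**2)))
    return coef, chi


def select_multistate(
    pool: list[tuple[str, SAXSProfile]],
    experiment: SAXSProfile,
    n_max: int = 4,
    max_pool: int = 50,
) -> EnsembleFitResult:
    """Exhaustive small-subset multistate selection against one experiment.

    For each ensemble size N = 1..n_max, every size-N subset of the pool is
    fitted (nonnegative weights + global scale, see :func:`_fit_subset`)
    and the subset with the lowest chi kept. The overall winner is the best
    chi across all N; exact ties resolve to the smaller N and then to
    lexicographically smaller label tuples.
    """
    if experiment.sigma is None:
        raise ValidationError("experimental profile must carry uncertainties")
    if len(pool) == 0:
        raise ValidationError("empty candidate pool")
    if len(pool) > max_pool:
        raise SizeError(
            f"pool of {len(pool)} exceeds the exhaustive-enumeration limit "
            f"({max_pool}); prune the pool first"
        )
    if not 1 <= n_max <= 5:
        raise ValidationError("n_max must be between 1 and 5")
    n_max = min(n_max, len(pool))

    # sort by label so subset enumeration order is the documented tie-break
    ordered = sorted(pool, key=lambda item: item[0])
    per_n: dict[int, dict] = {}
    best = None  # (chi, N, labels, weights, scale)
    for n in range(1, n_max + 1):
        best_n = None
        for combo in itertools.combinations(range(len(ordered)), n):
            labels = tuple(ordered[i][0] for i in combo)
            profiles = [ordered[i][1] for i in combo]
            coef, chi = _fit_subset(profiles, experiment)
            if best_n is None or chi < best_n[0] - 1e-12:
                best_n = (chi, labels, coef)
        chi, labels, coef = best_n
        total = coef.sum()
        if total <= 0:
            raise FitError(f"all-zero optimal weights for every size-{n} subset")
        per_n[n] = {
            "labels": labels,
            "weights": coef / total,
            "scale": float(total),
            "chi": chi,
        }
        if best is None or chi < best[0] - 1e-12:
            best = (chi, n, labels, coef / total, float(total))
    chi, _, labels, weights, scale = best
    return EnsembleFitResult(
        labels=labels, weights=weights, chi=chi, scale=scale, per_n=per_n
    )
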