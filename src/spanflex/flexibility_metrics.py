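"""Weighted flexibility and disorder measures over aligned ensembles.

After superposition on a reference subcomplex, the remaining state-to-state
variation of each rigid domain is summarized as:

- ``com_flexibility`` — weighted RMS dispersion of the domain's center of
  mass about its weighted mean position (nm);
- ``rotational_flexibility`` — weighted RMS rotation angle of the domain's
  orientation about the ensemble's mean orientation (degrees), with the
  mean orientation taken as the principal eigenvector of the weighted
  quaternion outer-product matrix;
- ``effective_disorder`` — the product of the two, a single per-domain
  disorder score (nm*deg);
- ``weight_entropy`` — the Shannon entropy of the state weights themselves
  (nats), a separate, information-theoretic quantity that is reported
  alongside but never conflated with the disorder score.

The radius of gyration is mass-weighted, with masses looked up by element.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble_io import (
    EnsembleAnnotation,
    StructureState,
    WeightedEnsemble,
    WeightedScalarDistribution,
)
from .errors import RankError, ResolutionError, ValidationError

__all__ = [
    "FlexibilityReport",
    "atomic_masses",
    "state_radius_of_gyration",
    "rg_distribution",
    "com_flexibility",
    "rotational_flexibility",
    "effective_disorder",
    "weight_entropy",
    "flexibility_report",
]

ANGSTROM_PER_NM = 10.0

# standard atomic weights for the elements seen in protein models
_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "CA": 40.078,  # calcium, only when the *element* field says CA
    "MN": 54.938,
    "CU": 63.546,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
}
_TWO_LETTER = {"SE", "FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR"}


def _element_of(atom_name: str) -> str:
    """Guess the element from a PDB atom name (CA -> C, FE1 -> FE)."""
    stripped = "".join(c for c in atom_name if c.isalpha()).upper()
    if stripped[:2] in _TWO_LETTER:
        return stripped[:2]
    return stripped[:1]


def atomic_masses(state: StructureState, indices: np.ndarray | None = None) -> np.ndarray:
    """Per-atom masses (Da); unknown elements fall back to carbon with a warning."""
    if indices is None:
        indices = np.arange(state.n_atoms)
    if state.elements is not None:
        symbols = [str(e).upper() for e in np.asarray(state.elements)[indices]]
    else:
        symbols = [_element_of(str(n)) for n in np.asarray(state.atom_names)[indices]]
    masses = np.empty(len(symbols))
    unknown = set()
    for i, sym in enumerate(symbols):
        m = _MASSES.get(sym)
        if m is None:
            unknown.add(sym)
            m = _MASSES["C"]
        masses[i] = m
    if unknown:
        warnings.warn(
            f"unknown element(s) {sorted(unknown)}; using carbon mass", stacklevel=2
        )
    return masses


def state_radius_of_gyration(state: StructureState) -> float:
    """Mass-weighted radius of gyration, in nm."""
    if state.n_atoms == 1:
        return 0.0
    m = atomic_masses(state)
    com = np.average(state.coords, axis=0, weights=m)
    r2 = np.sum((state.coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(r2, weights=m))) / ANGSTROM_PER_NM


def rg_distribution(ensemble: WeightedEnsemble, name: str = "Rg") -> WeightedScalarDistribution:
    """Weighted distribution of per-state radii of gyration (nm)."""
    values = np.array([state_radius_of_gyration(s) for s in ensemble.states])
    return WeightedScalarDistribution(values, ensemble.weights.copy(), unit="nm", name=name)


def _domain_com(state: StructureState, annotation: EnsembleAnnotation, domain: str) -> np.ndarray:
    idx = annotation.resolve(state, domain)
    m = atomic_masses(state, idx)
    return np.average(state.coords[idx], axis=0, weights=m)


def com_flexibility(
    ensemble: WeightedEnsemble, annotation: EnsembleAnnotation, domain: str
) -> float:
    """Weighted RMS dispersion (nm) of a domain's center of mass.

    sqrt( sum_i w_i ||c_i - c_bar||^2 ) with c_bar the weighted mean CoM;
    states must already be superposed on the reference.
    """
    coms = np.array([_domain_com(s, annotation, domain) for s in ensemble.states])
    w = ensemble.weights
    mean = np.average(coms, axis=0, weights=w)
    msd = float(np.sum(w * np.sum((coms - mean) ** 2, axis=1)))
    return np.sqrt(msd) / ANGSTROM_PER_NM


def _domain_orientations(
    ensemble: WeightedEnsemble, annotation: EnsembleAnnotation, domain: str
) -> Rotation:
    """Per-state rotation of the domain relative to state 1 (centered Kabsch)."""
    from .ensemble_geometry import kabsch  # late import: sibling module

    idx0 = annotation.resolve(ensemble.states[0], domain)
    base = ensemble.states[0].coords[idx0]
    if idx0.size < 3:
        raise RankError(f"domain {domain!r} needs >= 3 atoms for orientation")
    mats = []
    for state in ensemble.states:
        idx = annotation.resolve(state, domain)
        if idx.size != idx0.size:
            raise ResolutionError(
                f"domain {domain!r}: atom count differs between states"
            )
        tf = kabsch(base, state.coords[idx])
        mats.append(tf.rotation)
    return Rotation.from_matrix(np.array(mats))


def mean_orientation(rotations: Rotation, weights: np.ndarray) -> Rotation:
    """Weighted mean orientation: principal eigenvector of sum_i w_i q_i q_i^T.

    The quaternion outer product is sign-invariant, so the double cover of
    rotation space needs no explicit handling.
    """
    quats = rotations.as_quat()
    M = np.einsum("i,ij,ik->jk", weights, quats, quats)
    evals, evecs = np.linalg.eigh(M)
    return Rotation.from_quat(evecs[:, -1])


def rotational_flexibility(
    ensemble: WeightedEnsemble, annotation: EnsembleAnnotation, domain: str
) -> float:
    """Weighted RMS rotation angle (deg) of a domain about its mean orientation.

    Per state, the domain's best-fit rotation relative to state 1 is
    expressed as a quaternion; the mean orientation is the principal
    eigenvector of the weighted quaternion outer-product matrix, and the
    returned value is sqrt( sum_i w_i theta_i^2 ) with theta_i in
    [0, 180] degrees the geodesic angle from the mean.
    """
    rotations = _domain_orientations(ensemble, annotation, domain)
    mean = mean_orientation(rotations, ensemble.weights)
    rel = rotations * mean.inv()
    theta = np.degrees(rel.magnitude())  # in [0, 180] by construction
    return float(np.sqrt(np.sum(ensemble.weights * np.asarray(theta) ** 2)))


def effective_disorder(com_flex: float, rot_flex: float) -> float:
    """Per-domain disorder score: the exact product com_flex * rot_flex (nm*deg)."""
    if com_flex < 0 or rot_flex < 0:
        raise ValidationError("flexibility inputs must be non-negative")
    return com_flex * rot_flex


def weight_entropy(weights) -> float:
    """Shannon entropy (nats) of normalized state weights, 0*ln 0 := 0."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValidationError("negative weight")
    total = w.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValidationError("weights must be normalized")
    nz = w[w > 0]
    return float(-np.sum(nz * np.log(nz)))


@dataclass
class FlexibilityReport:
    """Full flexibility summary of one aligned ensemble."""

    rg_distribution: WeightedScalarDistribution
    domain_rows: list[dict]  # name, com_flex (nm), rot_flex (deg), effective_disorder
    weight_entropy: float

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.domain_rows,
            columns=["domain", "com_flex_nm", "rot_flex_deg", "effective_disorder"],
        )


def flexibility_report(
    ensemble: WeightedEnsemble,
    annotation: EnsembleAnnotation,
    whole_molecule: bool = True,
) -> FlexibilityReport:
    """Per-domain CoM/rotational flexibility plus a whole-molecule row.

    The whole-molecule row treats every atom as one body, giving the
    dispersion of the entire assembly about the aligned reference.
    """
    rows = []
    targets = list(annotation.domains)
    for domain in targets:
        cf = com_flexibility(ensemble, annotation, domain)
        rf = rotational_flexibility(ensemble, annotation, domain)
        rows.append(
            {
                "domain": domain,
                "com_flex_nm": cf,
                "rot_flex_deg": rf,
                "effective_disorder": effective_disorder(cf, rf),
            }
        )
    if whole_molecule:
        chains = sorted(set(np.concatenate([s.chain_ids for s in ensemble.states]).tolist()))
        expr = ",".join(chains)
        whole = EnsembleAnnotation(
            roles=dict(annotation.roles), domains={"__all__": expr}
        )
        cf = com_flexibility(ensemble, whole, "__all__")
        rf = rotational_flexibility(ensemble, whole, "__all__")
        rows.append(
            {
                "domain": "whole_molecule",
                "com_flex_nm": cf,
                "rot_flex_deg": rf,
                "effective_disorder": effective_disorder(cf, rf),
            }
        )
    return FlexibilityReport(
        rg_distribution=rg_distribution(ensemble),
        domain_rows=rows,
        weight_entropy=weight_entropy(ensemble.weights),
    )
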