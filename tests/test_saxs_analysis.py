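"""Debye profiles, Guinier/Kratky analysis, chi and multistate selection."""

import numpy as np
import pytest

import spanflex as sf
from spanflex.errors import FitError, SizeError, ValidationError

from conftest import make_state

Q = np.linspace(0.005, 0.4, 120)


def _sphere_state(radius=30.0, n=800, seed=0):
    return sf.uniform_ball_state(radius, n_beads=n, seed=seed)


# ---------------------------------------------------------------------------
# Debye profiles
# ---------------------------------------------------------------------------


def test_single_bead_is_flat_unity():
    profile = sf.debye_profile(make_state([[1.0, 2.0, 3.0]]), Q)
    assert np.allclose(profile.intensity, 1.0)


def test_two_bead_closed_form():
    d = 10.0
    profile = sf.debye_profile(make_state([[0, 0, 0], [0, 0, d]]), Q)
    expected = 2.0 * (1.0 + np.sin(Q * d) / (Q * d))
    assert np.allclose(profile.intensity, expected, atol=1e-10)


def test_debye_matches_double_loop_oracle(rng):
    """Random coil vs a naive O(n^2) per-q Debye sum."""
    coords = np.cumsum(rng.normal(size=(80, 3)) * 3.8, axis=0)
    state = make_state(coords)
    q_small = Q[::4]
    profile = sf.debye_profile(state, q_small)
    oracle = np.zeros_like(q_small)
    for a in range(80):
        for b in range(80):
            d = np.linalg.norm(coords[a] - coords[b])
            with np.errstate(invalid="ignore"):
                oracle += np.where(q_small * d == 0, 1.0, np.sin(q_small * d) / (q_small * d))
    assert np.allclose(profile.intensity, oracle, rtol=1e-10)


def test_debye_rigid_transform_invariance(rng):
    from scipy.spatial.transform import Rotation

    coords = rng.normal(size=(60, 3)) * 15
    rot = Rotation.random(random_state=np.random.RandomState(2)).as_matrix()
    p1 = sf.debye_profile(make_state(coords), Q)
    p2 = sf.debye_profile(make_state(coords @ rot.T + [40, -7, 3]), Q)
    assert np.allclose(p1.intensity, p2.intensity, rtol=1e-10)


# ---------------------------------------------------------------------------
# mixtures
# ---------------------------------------------------------------------------


def test_ensemble_profile_identities(rng):
    p = sf.debye_profile(make_state(rng.normal(size=(20, 3)) * 10), Q)
    same = sf.ensemble_profile([p], [1.0])
    assert np.allclose(same.intensity, p.intensity)
    fixed_point = sf.ensemble_profile([p, p], [0.3, 0.7])
    assert np.allclose(fixed_point.intensity, p.intensity, rtol=1e-12)


def test_ensemble_profile_manual_sum(rng):
    profiles = [
        sf.debye_profile(make_state(rng.normal(size=(15, 3)) * 12), Q) for _ in range(3)
    ]
    w = np.array([0.5, 0.3, 0.2])
    mixed = sf.ensemble_profile(profiles, w)
    manual = sum(wi * p.intensity for wi, p in zip(w, profiles))
    assert np.allclose(mixed.intensity, manual, atol=1e-12)


def test_ensemble_profile_grid_mismatch(rng):
    p1 = sf.debye_profile(make_state(rng.normal(size=(10, 3))), Q)
    p2 = sf.debye_profile(make_state(rng.normal(size=(10, 3))), Q * 1.01)
    with pytest.raises(ValidationError):
        sf.ensemble_profile([p1, p2], [0.5, 0.5])


# ---------------------------------------------------------------------------
# Guinier and Kratky
# ---------------------------------------------------------------------------


def test_guinier_recovers_exact_parameters():
    rg_true, i0_true = 20.0, 7.0
    q = np.linspace(0.002, 0.2, 150)
    profile = sf.SAXSProfile(q, i0_true * np.exp(-(q**2) * rg_true**2 / 3))
    fit = sf.guinier_fit(profile)
    assert fit.rg == pytest.approx(rg_true, rel=1e-3)
    assert fit.i0 == pytest.approx(i0_true, rel=1e-3)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_guinier_sphere_analytic(seed):
    """Uniform-ball bead model: Guinier Rg within 2% of sqrt(3/5) R.

    The Guinier approximation carries a known systematic bias for compact
    globular particles at the standard qRg <= 1.3 data window, so the
    validation against the analytic sphere uses the tighter qRg <= 1.0.
    """
    R = 30.0
    profile = sf.debye_profile(_sphere_state(R, seed=seed), np.linspace(0.004, 0.1, 80))
    fit = sf.guinier_fit(profile, qrg_max=1.0)
    assert fit.rg == pytest.approx(np.sqrt(3 / 5) * R, rel=0.02)


def test_guinier_stable_under_one_percent_noise(rng):
    R = 30.0
    q = np.linspace(0.004, 0.1, 80)
    clean = sf.debye_profile(_sphere_state(R), q)
    rg0 = sf.guinier_fit(clean).rg
    noisy = sf.SAXSProfile(
        q, clean.intensity * (1 + 0.01 * rng.normal(size=q.size))
    )
    assert sf.guinier_fit(noisy).rg == pytest.approx(rg0, rel=0.05)


def test_guinier_rejects_rising_curve():
    q = np.linspace(0.01, 0.1, 50)
    with pytest.raises(FitError):
        sf.guinier_fit(sf.SAXSProfile(q, np.exp(+(q**2) * 100)))


def test_kratky_peak_of_gaussian_form():
    rg, i0 = 20.0, 7.0
    q = np.linspace(0.001, 0.25, 4000)
    profile = sf.SAXSProfile(q, i0 * np.exp(-(q**2) * rg**2 / 3))
    curve = sf.dimensionless_kratky(profile, rg, i0)
    x_peak, y_peak = curve.peak()
    assert x_peak == pytest.approx(np.sqrt(3.0), rel=0.005)
    assert y_peak == pytest.approx(3.0 / np.e, rel=0.005)


def test_kratky_point_scatterer_is_parabola():
    q = np.linspace(0.01, 0.5, 60)
    profile = sf.SAXSProfile(q, np.full_like(q, 5.0))
    curve = sf.dimensionless_kratky(profile, 10.0, 5.0)
    assert np.allclose(curve.y, curve.x**2, rtol=1e-12)


def test_flexible_ensemble_has_higher_kratky_amplitude(tce_template, rng):
    """Amplitude criterion: a flexible chain ensemble sits above a compact
    globular particle at qRg >= 2 on the dimensionless Kratky plot."""
    q = np.linspace(0.004, 0.35, 250)
    globular = sf.debye_profile(_sphere_state(radius=30.0), q)
    fit_g = sf.guinier_fit(globular)
    kratky_g = sf.dimensionless_kratky(globular, fit_g.rg, fit_g.i0)

    ens, _ = sf.sample_conformations(tce_template, 40, kappa=120.0, seed=8)
    mixed = sf.ensemble_profile(
        [sf.debye_profile(s, q) for s in ens.states], ens.weights
    )
    fit_f = sf.guinier_fit(mixed)
    kratky_f = sf.dimensionless_kratky(mixed, fit_f.rg, fit_f.i0)

    lo, hi = 2.0, min(kratky_g.x.max(), kratky_f.x.max())
    grid = np.linspace(lo, hi, 50)
    y_g = np.interp(grid, kratky_g.x, kratky_g.y)
    y_f = np.interp(grid, kratky_f.x, kratky_f.y)
    assert np.all(y_f > y_g)


# ---------------------------------------------------------------------------
# chi goodness of fit
# ---------------------------------------------------------------------------


def _chi_profiles(rng):
    model = sf.debye_profile(make_state(rng.normal(size=(25, 3)) * 12), Q)
    sigma = 0.02 * model.intensity
    return model, sigma


def test_chi_exact_proportionality(rng):
    model, sigma = _chi_profiles(rng)
    experiment = sf.SAXSProfile(Q, 3.7 * model.intensity, sigma)
    chi, scale = sf.chi_fit(model, experiment)
    assert chi == pytest.approx(0.0, abs=1e-10)
    assert scale == pytest.approx(3.7)


def test_chi_unit_residuals(rng):
    model, sigma = _chi_profiles(rng)
    signs = np.where(np.arange(Q.size) % 2 == 0, 1.0, -1.0)
    experiment = sf.SAXSProfile(Q, model.intensity + signs * sigma, sigma)
    chi, scale = sf.chi_fit(model, experiment)
    # alternating +/- sigma residuals are orthogonal to the model: chi = 1
    assert chi == pytest.approx(1.0, abs=0.02)


def test_chi_scale_invariance(rng):
    model, sigma = _chi_profiles(rng)
    experiment = sf.SAXSProfile(
        Q, model.intensity * (1 + 0.05 * rng.normal(size=Q.size)), sigma
    )
    chi1, _ = sf.chi_fit(model, experiment)
    for alpha in (0.1, 3.0, 250.0):
        scaled = sf.SAXSProfile(Q, alpha * model.intensity)
        chi2, _ = sf.chi_fit(scaled, experiment)
        assert chi2 == pytest.approx(chi1, rel=1e-9)


def test_chi_matches_grid_search_oracle(rng):
    model, sigma = _chi_profiles(rng)
    experiment = sf.SAXSProfile(
        Q, 2.2 * model.intensity + sigma * rng.normal(size=Q.size), sigma
    )
    chi, scale = sf.chi_fit(model, experiment)
    grid = np.linspace(scale * 0.9, scale * 1.1, 20001)
    chis = np.sqrt(
        np.mean(
            ((experiment.intensity[None] - grid[:, None] * model.intensity[None])
             / sigma[None]) ** 2,
            axis=1,
        )
    )
    assert chi == pytest.approx(chis.min(), abs=1e-6)


def test_chi_non_overlapping_ranges(rng):
    model, sigma = _chi_profiles(rng)
    far = sf.SAXSProfile(Q + 10.0, model.intensity, sigma)
    with pytest.raises(ValidationError):
        sf.chi_fit(model, far)


# ---------------------------------------------------------------------------
# multistate selection
# ---------------------------------------------------------------------------


Q_FIT = np.linspace(0.005, 0.5, 600)
_POOL_CACHE = {}


def _profile_pool(tce_template, n=10, seed=300):
    """Mutually distinct single-state pool: 30 floppy conformers pruned to n."""
    key = (n, seed)
    if key not in _POOL_CACHE:
        candidates = []
        for i in range(30):
            ens, _ = sf.sample_conformations(tce_template, 1, kappa=150.0, seed=seed + i)
            candidates.append((f"s{i:02d}", sf.debye_profile(ens.states[0], Q_FIT)))
        _POOL_CACHE[key] = sf.prune_pool(candidates, max_size=n)
    return _POOL_CACHE[key]


def test_exact_member_selected(tce_template):
    pool = _profile_pool(tce_template, n=5)
    label, target = pool[2]
    experiment = sf.SAXSProfile(Q_FIT, target.intensity, 0.01 * target.intensity)
    result = sf.select_multistate(pool, experiment, n_max=1)
    assert result.labels == (label,)
    assert result.weights[0] == pytest.approx(1.0)
    assert result.chi == pytest.approx(0.0, abs=1e-8)


def test_noiseless_mixture_weights_recovered(tce_template):
    pool = _profile_pool(tce_template, n=6)
    la, lb = pool[1][0], pool[4][0]
    mix = 0.7 * pool[1][1].intensity + 0.3 * pool[4][1].intensity
    experiment = sf.SAXSProfile(Q_FIT, mix, 0.01 * mix)
    result = sf.select_multistate(pool, experiment, n_max=2)
    weights = dict(zip(result.labels, result.weights))
    assert weights.get(la, 0.0) == pytest.approx(0.7, abs=1e-3)
    assert weights.get(lb, 0.0) == pytest.approx(0.3, abs=1e-3)


def test_noisy_mixture_true_pair_from_ten(tce_template):
    pool = _profile_pool(tce_template, n=10)
    la, lb = pool[2][0], pool[8][0]
    mix = 0.7 * pool[2][1].intensity + 0.3 * pool[8][1].intensity
    sigma = 0.03 * mix
    noisy = mix + sigma * np.random.default_rng(42).normal(size=mix.size)
    experiment = sf.SAXSProfile(Q_FIT, noisy, sigma)
    result = sf.select_multistate(pool, experiment, n_max=2)
    weights = dict(zip(result.per_n[2]["labels"], result.per_n[2]["weights"]))
    assert set(result.per_n[2]["labels"]) == {la, lb}
    assert weights[la] == pytest.approx(0.7, abs=0.05)
    assert weights[lb] == pytest.approx(0.3, abs=0.05)


def test_chi_non_increasing_in_n(tce_template):
    pool = _profile_pool(tce_template, n=7)
    mix = sum(0.25 * pool[i][1].intensity for i in (0, 2, 4, 6))
    sigma = 0.02 * mix
    noisy = mix + sigma * np.random.default_rng(5).normal(size=mix.size)
    experiment = sf.SAXSProfile(Q_FIT, noisy, sigma)
    result = sf.select_multistate(pool, experiment, n_max=4)
    chis = [result.per_n[n]["chi"] for n in sorted(result.per_n)]
    assert all(b <= a + 1e-9 for a, b in zip(chis, chis[1:]))


def test_prune_pool_enforces_distinctness(tce_template):
    pool = _profile_pool(tce_template, n=10)
    assert len(pool) == 10
    assert [lbl for lbl, _ in pool] == sorted(lbl for lbl, _ in pool)
    for i in range(10):
        for j in range(i + 1, 10):
            pseudo = sf.SAXSProfile(
                Q_FIT, pool[j][1].intensity, 0.03 * pool[j][1].intensity
            )
            chi, _ = sf.chi_fit(pool[i][1], pseudo)
            assert chi > 0.5  # members distinguishable at the noise level


def test_pool_size_limit(tce_template, rng):
    p = sf.debye_profile(make_state(rng.normal(size=(10, 3)) * 10), Q)
    pool = [(f"p{i}", p) for i in range(51)]
    experiment = sf.SAXSProfile(Q, p.intensity, 0.01 * p.intensity)
    with pytest.raises(SizeError):
        sf.select_multistate(pool, experiment)
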