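"""Ensemble, weight-table, SAXS-curve and report I/O."""

import io

import numpy as np
import pytest

import spanflex as sf
from spanflex.errors import ParseError, StructuralError, ValidationError

from conftest import dummy_annotation, make_state


# ---------------------------------------------------------------------------
# weighted quantiles
# ---------------------------------------------------------------------------


def brute_force_quantile(values, weights, q):
    """Independent scan: interpolate between cumulative-span midpoints."""
    pairs = sorted(zip(values, weights))
    w = np.array([p[1] for p in pairs], dtype=float)
    w = w / w.sum()
    v = [p[0] for p in pairs]
    knots = []
    cum = 0.0
    for wi in w:
        knots.append(cum + wi / 2.0)
        cum += wi
    if q <= knots[0]:
        return v[0]
    if q >= knots[-1]:
        return v[-1]
    for k in range(len(knots) - 1):
        if knots[k] <= q <= knots[k + 1]:
            frac = (q - knots[k]) / (knots[k + 1] - knots[k])
            return v[k] + frac * (v[k + 1] - v[k])
    raise AssertionError("unreachable")


def test_single_value_is_every_quantile():
    for q in (0.25, 0.5, 0.75):
        assert sf.weighted_quantile([10.0], [1.0], q) == 10.0


def test_equal_weight_pair_median_interpolates():
    assert sf.weighted_quantile([1.0, 3.0], [0.5, 0.5], 0.5) == pytest.approx(2.0)


def test_quantiles_match_brute_force_scan(rng):
    values = rng.normal(size=1000)
    weights = rng.uniform(0.1, 2.0, size=1000)
    for q in (0.1, 0.25, 0.5, 0.75, 0.9):
        assert sf.weighted_quantile(values, weights, q) == pytest.approx(
            brute_force_quantile(values, weights, q), abs=1e-12
        )


def test_quantile_ordering_invariant(rng):
    for _ in range(20):
        n = int(rng.integers(2, 50))
        d = sf.WeightedScalarDistribution(
            rng.normal(size=n), rng.uniform(0.01, 1, size=n), "nm"
        )
        assert d.min <= d.q1 <= d.median <= d.q3 <= d.max


# ---------------------------------------------------------------------------
# weights and ensembles
# ---------------------------------------------------------------------------


def test_raw_weights_are_renormalized():
    states = [make_state([[0, 0, float(i)]], label=f"s{i}") for i in range(3)]
    ens = sf.WeightedEnsemble(states, np.array([2.0, 1.0, 1.0]))
    assert np.allclose(ens.weights, [0.5, 0.25, 0.25])
    # idempotent
    again = sf.WeightedEnsemble(ens.states, ens.weights)
    assert np.allclose(again.weights, ens.weights)
    assert abs(again.weights.sum() - 1.0) < 1e-9


def test_negative_weight_rejected():
    with pytest.raises(ValidationError):
        sf.WeightedEnsemble([make_state([[0, 0, 0]])], np.array([-1.0]))


def test_state_weight_count_mismatch():
    with pytest.raises(StructuralError):
        sf.WeightedEnsemble([make_state([[0, 0, 0]])], np.array([0.5, 0.5]))


def test_weight_table_dialects(tmp_path):
    p = tmp_path / "w.tsv"
    p.write_text("# comment\nmodelA\t2.0\nmodelB,1.0\nmodelC 1.0\n")
    rows = sf.ensemble_io.read_weight_table(p)
    assert rows == [("modelA", 2.0), ("modelB", 1.0), ("modelC", 1.0)]


def test_single_state_identity(tmp_path, tce_template):
    ens, _ = sf.sample_conformations(tce_template, 1, kappa=20.0, seed=3)
    sf.write_multistate(ens, tmp_path / "m.pdb", tmp_path / "w.tsv")
    back = sf.read_multistate(tmp_path / "m.pdb", tmp_path / "w.tsv")
    assert len(back) == 1
    assert np.allclose(back.weights, [1.0])
    assert np.allclose(back.states[0].coords, ens.states[0].coords)


def test_multistate_roundtrip_exact(tmp_path, tce_template):
    ens, _ = sf.sample_conformations(
        tce_template, 8, kappa=40.0, seed=9, weight_mode="dirichlet"
    )
    sf.write_multistate(ens, tmp_path / "m.pdb", tmp_path / "w.tsv")
    back = sf.read_multistate(tmp_path / "m.pdb", tmp_path / "w.tsv")
    assert len(back) == 8
    assert np.allclose(back.weights, ens.weights, rtol=1e-9)
    for a, b in zip(back.states, ens.states):
        assert np.array_equal(a.coords, b.coords)  # coordinates are grid-quantized
        assert np.array_equal(a.chain_ids, b.chain_ids)
        assert np.array_equal(a.res_ids, b.res_ids)


def test_label_mismatch_reported(tmp_path, tce_template):
    ens, _ = sf.sample_conformations(tce_template, 2, kappa=10.0, seed=1)
    sf.write_multistate(ens, tmp_path / "m.pdb", tmp_path / "w.tsv")
    with pytest.raises(StructuralError, match="nosuch"):
        sf.read_multistate(tmp_path / "m.pdb", [("1", 0.5), ("nosuch", 0.5)])
    with pytest.raises(StructuralError):
        sf.read_multistate(tmp_path / "m.pdb", [("1", 1.0)])  # count mismatch


def test_missing_pdb_is_parse_error(tmp_path):
    with pytest.raises(ParseError, match="not_there"):
        sf.read_multistate([tmp_path / "not_there.pdb"], [("x", 1.0)])


def test_order_invariance_of_downstream_statistics(tce_template):
    """Permuting states together with their weights changes nothing."""
    ens, _ = sf.sample_conformations(
        tce_template, 30, kappa=40.0, seed=2, weight_mode="dirichlet"
    )
    ann = sf.template_annotation(tce_template)
    perm = np.random.default_rng(0).permutation(30)
    permuted = sf.WeightedEnsemble(
        [ens.states[i] for i in perm], ens.weights[perm]
    )
    d1 = sf.spacing_distribution(ens, ann, "anchor_1", "anchor_2")
    d2 = sf.spacing_distribution(permuted, ann, "anchor_1", "anchor_2")
    for q in (0.25, 0.5, 0.75):
        assert d1.quantile(q) == pytest.approx(d2.quantile(q), abs=1e-12)


# ---------------------------------------------------------------------------
# annotation config
# ---------------------------------------------------------------------------


def test_annotation_well_formed():
    ann = dummy_annotation()
    assert set(sf.ensemble_io.REQUIRED_ROLES) <= set(ann.roles)


def test_annotation_missing_role_named():
    roles = {r: "A:1" for r in sf.ensemble_io.REQUIRED_ROLES if r != "anchor_2"}
    with pytest.raises(ValidationError, match="anchor_2"):
        sf.EnsembleAnnotation(roles=roles)


def test_annotation_roundtrip(tce_template, tmp_path):
    ann = sf.template_annotation(tce_template)
    path = tmp_path / "ann.yaml"
    sf.ensemble_io.serialize_annotation(ann, path)
    back = sf.parse_annotation(path)
    assert back.roles == ann.roles
    assert back.domains == ann.domains
    assert sf.ensemble_io.serialize_annotation(back) == sf.ensemble_io.serialize_annotation(ann)


def test_annotation_malformed_term():
    with pytest.raises(ValidationError):
        sf.parse_annotation(
            {"roles": {**{r: "A:1" for r in sf.ensemble_io.REQUIRED_ROLES},
                       "axis_head": "A:??"}}
        )


# ---------------------------------------------------------------------------
# SAXS curve I/O
# ---------------------------------------------------------------------------


def test_saxs_read_basic():
    text = "# q I sigma\n" + "\n".join(
        f"{0.01 * (i + 1)} {100 - i} {1.0}" for i in range(100)
    )
    profile = sf.read_saxs_profile(io.StringIO(text))
    assert len(profile) == 100
    assert np.all(np.diff(profile.q) > 0)


def test_saxs_shuffled_rows_sorted_with_warning(rng):
    rows = [(0.01 * (i + 1), 100.0 - i) for i in range(20)]
    rng.shuffle(rows)
    text = "\n".join(f"{q} {i}" for q, i in rows)
    with pytest.warns(UserWarning, match="sorting"):
        profile = sf.read_saxs_profile(io.StringIO(text))
    assert np.all(np.diff(profile.q) > 0)
    # missing sigma imputed as the configurable fraction of I
    assert np.allclose(profile.sigma, 0.03 * profile.intensity)


def test_saxs_roundtrip(tmp_path, tce_template):
    ens, _ = sf.sample_conformations(tce_template, 1, kappa=0.0, seed=0)
    q = np.linspace(0.01, 0.3, 50)
    profile = sf.debye_profile(ens.states[0], q)
    profile.sigma = 0.02 * profile.intensity
    path = tmp_path / "p.dat"
    sf.write_saxs_profile(profile, path)
    back = sf.read_saxs_profile(path)
    assert np.allclose(back.q, profile.q, rtol=1e-12)
    assert np.allclose(back.intensity, profile.intensity, rtol=1e-12)
    assert np.allclose(back.sigma, profile.sigma, rtol=1e-12)


def test_saxs_parse_errors():
    with pytest.raises(ParseError, match="line 3"):
        sf.read_saxs_profile(io.StringIO("0.1 1\n0.2 1\n0.3 oops\n0.4 1\n0.5 1\n"))
    with pytest.raises(ValidationError):
        sf.read_saxs_profile(
            io.StringIO("\n".join(f"{0.1 * (i + 1)} -1.0" for i in range(6)))
        )


# ---------------------------------------------------------------------------
# distribution report
# ---------------------------------------------------------------------------


def test_report_single_value(tmp_path):
    d = sf.WeightedScalarDistribution([10.0], [1.0], "nm", name="x")
    frame = sf.write_distribution_report([d], tmp_path / "r.csv")
    row = frame.iloc[0]
    assert row["median"] == row["q1"] == row["q3"] == 10.0
    assert list(frame.columns) == sf.ensemble_io.REPORT_COLUMNS


def test_report_symmetric_pair():
    d = sf.WeightedScalarDistribution([1.0, 3.0], [0.5, 0.5], "nm")
    frame = sf.write_distribution_report([d])
    assert frame.iloc[0]["median"] == pytest.approx(2.0)


def test_report_matches_brute_force(rng):
    values = rng.normal(5, 2, size=1000)
    weights = rng.uniform(0.5, 1.5, size=1000)
    d = sf.WeightedScalarDistribution(values, weights, "nm")
    frame = sf.write_distribution_report([d])
    row = frame.iloc[0]
    assert row["median"] == pytest.approx(brute_force_quantile(values, weights, 0.5))
    assert row["q1"] == pytest.approx(brute_force_quantile(values, weights, 0.25))
    assert row["q3"] == pytest.approx(brute_force_quantile(values, weights, 0.75))
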