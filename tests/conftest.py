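import numpy as np
import pytest

import spanflex as sf
from spanflex.synthetic_data import ArticulatedTemplate, DomainSpec, JointSpec


def make_state(coords, label="s", chain="A", atom_name="CA", element="C"):
    """Minimal single-chain state from raw coordinates (Angstrom)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return sf.StructureState(
        serial=np.arange(1, n + 1),
        chain_ids=np.full(n, chain),
        res_ids=np.arange(1, n + 1),
        res_names=np.full(n, "ALA"),
        atom_names=np.full(n, atom_name),
        coords=coords,
        label=label,
        elements=np.full(n, element),
    )


def dummy_annotation(domains=None, **role_overrides):
    """Annotation with all required roles resolvable on chain-A states."""
    roles = {
        "paratope_tip_1": "A:1",
        "paratope_tip_2": "A:2",
        "anchor_1": "A:1",
        "anchor_2": "A:2",
        "reference": "A",
        "axis_head": "A:1",
        "axis_tail": "A:2",
    }
    roles.update(role_overrides)
    return sf.EnsembleAnnotation(roles=roles, domains=domains or {"body": "A"})


def two_rod_template(kappa=50.0, twist=0.0):
    """Two-rod articulated template: static base (reference) + hinged arm."""
    return ArticulatedTemplate(
        domains=[DomainSpec("base", 16, "rod", 2.0), DomainSpec("arm", 16, "rod", 2.0)],
        joints=[JointSpec(kappa, twist)],
        landmarks={
            "anchor_1": ("base", 0),
            "anchor_2": ("arm", 15),
            "paratope_tip_1": ("base", 15),
            "paratope_tip_2": ("arm", 0),
            "axis_head": ("base", 0),
            "axis_tail": ("base", 15),
        },
        reference_domains=["base"],
    )


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tce_template():
    return sf.tce_like_template()


@pytest.fixture(scope="session")
def tce_ensemble(tce_template):
    """Mid-flexibility 100-state ensemble with Dirichlet weights, aligned."""
    ensemble, truth = sf.sample_conformations(
        tce_template, 100, kappa=40.0, seed=11, weight_mode="dirichlet"
    )
    annotation = sf.template_annotation(tce_template)
    aligned, _, _ = sf.superpose_states(ensemble, annotation)
    return aligned, truth, annotation
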