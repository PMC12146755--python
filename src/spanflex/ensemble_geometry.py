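"""Rigid superposition and weighted spacing/tilt geometry of ensembles.

All states are first superposed on a common reference subcomplex (e.g. the
tumor-antigen arm of a T cell engager in complex with its antigen), after
which landmark spacings — paratope-tip to paratope-tip, membrane anchor to
membrane anchor — and domain tilt angles are collected into weighted
distributions. Spacings are reported in nm; coordinates stay in Angstrom
internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ensemble_io import (
    EnsembleAnnotation,
    StructureState,
    WeightedEnsemble,
    WeightedScalarDistribution,
)
from .errors import RankError, ResolutionError, ValidationError

__all__ = [
    "RigidTransform",
    "kabsch",
    "superpose_states",
    "selection_centroid",
    "spacing_distribution",
    "tilt_angle_distribution",
]

ANGSTROM_PER_NM = 10.0


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValidationError("rotation must be 3x3 and translation length 3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValidationError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValidationError("rotation determinant is not +1 (improper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit of ``mobile`` onto ``target`` (same atom order).

    Returns the proper rotation + translation minimizing the RMSD between
    the transformed mobile points and the target points. Raises
    :class:`RankError` for fewer than 3 points or a collinear point set,
    where the rotation about the line is unconstrained.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ResolutionError("point sets must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise RankError("rigid fit needs at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    scale = max(np.linalg.norm(P0), np.linalg.norm(Q0), 1.0)
    if S[1] <= 1e-9 * scale**2:
        raise RankError("reference points are collinear; rotation under-determined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    return RigidTransform(R, t)


def superpose_states(
    ensemble: WeightedEnsemble,
    annotation: EnsembleAnnotation,
    reference_role: str = "reference",
):
    """Superpose every state on state 1 via the reference selection.

    Each state is rigidly transformed by the Kabsch fit of its reference
    atoms onto the first state's reference atoms (first state = first row
    of the weight table; the first state itself gets the identity).

    Returns ``(aligned_ensemble, transforms, reference_rmsds)`` where the
    RMSD (A) is computed over the reference selection after alignment.
    """
    ref_idx0 = annotation.resolve(ensemble.states[0], reference_role)
    target = ensemble.states[0].coords[ref_idx0]
    aligned, transforms, rmsds = [], [], []
    for k, state in enumerate(ensemble.states):
        idx = annotation.resolve(state, reference_role)
        if idx.size != ref_idx0.size:
            raise ResolutionError(
                f"reference selection resolves to {idx.size} atoms in state "
                f"{state.label!r} but {ref_idx0.size} in state {ensemble.states[0].label!r}"
            )
        if k == 0:
            tf = RigidTransform.identity()
        else:
            tf = kabsch(state.coords[idx], target)
        moved = state.transformed(tf.rotation, tf.translation)
        rmsd = float(
            np.sqrt(np.mean(np.sum((moved.coords[idx] - target) ** 2, axis=1)))
        )
        aligned.append(moved)
        transforms.append(tf)
        rmsds.append(rmsd)
    return WeightedEnsemble(aligned, ensemble.weights.copy()), transforms, rmsds


def selection_centroid(
    state: StructureState, annotation: EnsembleAnnotation, role: str
) -> np.ndarray:
    """Unweighted mean position (A) of the atoms a role resolves to."""
    idx = annotation.resolve(state, role)
    return state.coords[idx].mean(axis=0)


def spacing_distribution(
    ensemble: WeightedEnsemble,
    annotation: EnsembleAnnotation,
    role_a: str,
    role_b: str,
    name: str = "",
) -> WeightedScalarDistribution:
    """Weighted distribution of centroid-to-centroid distances (nm).

    The per-state Euclidean distance between the two role centroids, paired
    with the state weights. Rigid alignment does not change it.
    """
    values = np.empty(len(ensemble))
    for i, state in enumerate(ensemble.states):
        ca = selection_centroid(state, annotation, role_a)
        cb = selection_centroid(state, annotation, role_b)
        values[i] = np.linalg.norm(ca - cb) / ANGSTROM_PER_NM
    return WeightedScalarDistribution(
        values, ensemble.weights.copy(), unit="nm", name=name or f"{role_a}-{role_b}"
    )


def _principal_axis(coords: np.ndarray):
    """Longest principal axis of a point cloud and its axis-definedness.

    Returns (unit vector, relative gap between the top two covariance
    eigenvalues). A gap below ~1% marks a near-spherical domain whose
    longest axis is ill-defined.
    """
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    axis = evecs[:, -1]
    top, second = evals[-1], evals[-2]
    gap = (top - second) / top if top > 0 else 0.0
    return axis / np.linalg.norm(axis), gap


def tilt_angle_distribution(
    ensemble: WeightedEnsemble,
    annotation: EnsembleAnnotation,
    domain: str,
    axis_head: str = "axis_head",
    axis_tail: str = "axis_tail",
    name: str = "",
):
    """Weighted tilt angles (deg) of a domain against a molecular axis.

    For each (previously superposed) state: the acute angle between the
    domain's longest principal axis and the axis_head -> axis_tail unit
    vector, folded into [0, 90] degrees because a principal axis has no
    sign. Near-spherical domains (top two covariance eigenvalues within 1%)
    are flagged and a warning emitted; their angles are still reported.

    Returns ``(distribution, flagged_labels)``.
    """
    angles = np.empty(len(ensemble))
    flagged: list[str] = []
    for i, state in enumerate(ensemble.states):
        head = selection_centroid(state, annotation, axis_head)
        tail = selection_centroid(state, annotation, axis_tail)
        axis = tail - head
        norm = np.linalg.norm(axis)
        if norm <= 0.1:
            raise ValidationError(
                f"axis endpoints closer than 0.1 A in state {state.label!r}"
            )
        axis /= norm
        idx = annotation.resolve(state, domain)
        if idx.size < 2:
            raise ResolutionError(f"domain {domain!r} needs >= 2 atoms for an axis")
        dom_axis, gap = _principal_axis(state.coords[idx])
        if gap < 0.01:
            flagged.append(state.label)
        cosang = abs(float(np.dot(dom_axis, axis)))
        angles[i] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if flagged:
        warnings.warn(
            f"domain {domain!r}: near-spherical in state(s) {flagged}; "
            "tilt axis ill-defined",
            stacklevel=2,
        )
    dist = WeightedScalarDistribution(
        angles, ensemble.weights.copy(), unit="deg", name=name or f"tilt[{domain}]"
    )
    return dist, flagged
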