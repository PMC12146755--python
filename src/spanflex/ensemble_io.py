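"""I/O and core containers for weighted multistate ensembles.

A multistate ensemble is a set of 3D conformations ("states") of one
molecule, each carrying a fractional weight describing its effective
contribution to the solution ensemble (as produced by multistate fitting
of SAXS data). This module reads/writes the standard on-disk forms —
PDB models, two-column weight tables, 3-column SAXS curves — and defines
the in-memory containers every downstream analysis operates on.

Internal length unit is Angstrom (PDB native); distances are converted to
nanometres only at the reporting boundary.
"""

from __future__ import annotations

import io
import os
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

from .errors import (
    ParseError,
    ResolutionError,
    StructuralError,
    ValidationError,
)

__all__ = [
    "StructureState",
    "WeightedEnsemble",
    "EnsembleAnnotation",
    "WeightedScalarDistribution",
    "weighted_quantile",
    "read_multistate",
    "write_multistate",
    "read_weight_table",
    "parse_annotation",
    "serialize_annotation",
    "read_saxs_profile",
    "write_saxs_profile",
    "write_distribution_report",
]

#: required selection roles every annotation must declare
REQUIRED_ROLES = (
    "paratope_tip_1",
    "paratope_tip_2",
    "anchor_1",
    "anchor_2",
    "reference",
    "axis_head",
    "axis_tail",
)

_TERM_RE = re.compile(
    r"^(?P<chain>[A-Za-z0-9]+)"
    r"(?::(?P<res>\*|\d+(?:-\d+)?))?"
    r"(?::(?P<atom>[A-Za-z0-9'*]+))?$"
)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class StructureState:
    """One labeled conformation: parallel per-atom arrays, coordinates in A.

    Parameters
    ----------
    serial : integer atom ids
    chain_ids : chain identifier per atom
    res_ids : residue sequence number per atom
    res_names : residue name per atom
    atom_names : atom name per atom
    coords : (n_atoms, 3) float array, Angstrom
    label : source identifier (file stem or model number)
    elements : optional element symbol per atom; guessed from the atom
        name when absent
    """

    serial: np.ndarray
    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray
    label: str = ""
    elements: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be an (n, 3) array")
        n = self.coords.shape[0]
        if n == 0:
            raise ValidationError("a state must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"non-finite coordinates in state {self.label!r}")
        for name in ("serial", "chain_ids", "res_ids", "res_names", "atom_names"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValidationError(f"{name} length {arr.shape[0]} != {n} atoms")
            setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def select(self, expression: str) -> np.ndarray:
        """Resolve a selection expression to atom indices.

        Grammar: comma-separated union of ``CHAIN[:RESRANGE[:ATOM]]`` terms,
        where RESRANGE is ``lo-hi``, a single residue number, or ``*``.
        Examples: ``"H:98-100:CA"``, ``"C"``, ``"A:*:CA,B:*:CA"``.
        """
        mask = np.zeros(self.n_atoms, dtype=bool)
        for term in str(expression).split(","):
            term = term.strip()
            if not term:
                continue
            m = _TERM_RE.match(term)
            if m is None:
                raise ValidationError(f"malformed selection term {term!r}")
            sub = self.chain_ids == m.group("chain")
            res = m.group("res")
            if res and res != "*":
                if "-" in res:
                    lo, hi = (int(x) for x in res.split("-"))
                else:
                    lo = hi = int(res)
                sub &= (self.res_ids >= lo) & (self.res_ids <= hi)
            atom = m.group("atom")
            if atom and atom != "*":
                sub &= self.atom_names == atom
            mask |= sub
        return np.flatnonzero(mask)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureState":
        """Return a copy with coordinates mapped through x -> R x + t."""
        new = StructureState(
            serial=self.serial,
            chain_ids=self.chain_ids,
            res_ids=self.res_ids,
            res_names=self.res_names,
            atom_names=self.atom_names,
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
            label=self.label,
            elements=self.elements,
        )
        return new


def _normalize_weights(weights: Sequence[float]) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1:
        raise ValidationError("weights must be one-dimensional")
    if np.any(w < 0):
        raise ValidationError("negative state weight")
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValidationError("weights must sum to a positive finite value")
    return w / total


@dataclass
class WeightedEnsemble:
    """States plus normalized effective weights; the unit of all analyses."""

    states: list[StructureState]
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.states):
            raise StructuralError(
                f"{len(self.states)} states but {len(self.weights)} weights"
            )
        if len(self.states) == 0:
            raise ValidationError("ensemble must contain at least one state")
        self.weights = _normalize_weights(self.weights)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]


@dataclass
class EnsembleAnnotation:
    """Named atom selections: landmark roles plus a domain decomposition.

    ``roles`` carries the seven required landmarks (paratope tips, membrane
    anchors, superposition reference, axis endpoints); ``domains`` names the
    rigid bodies whose flexibility is analysed.
    """

    roles: dict[str, str]
    domains: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [r for r in REQUIRED_ROLES if r not in self.roles]
        if missing:
            raise ValidationError(
                "annotation is missing required role(s): " + ", ".join(missing)
            )

    def expression(self, name: str) -> str:
        if name in self.roles:
            return self.roles[name]
        if name in self.domains:
            return self.domains[name]
        raise ValidationError(f"unknown selection name {name!r}")

    def resolve(self, state: StructureState, name: str) -> np.ndarray:
        idx = state.select(self.expression(name))
        if idx.size == 0:
            raise ResolutionError(
                f"selection {name!r} resolves to no atoms in state {state.label!r}"
            )
        return idx

    def coverage_report(self, state: StructureState) -> dict[str, int]:
        """Atom count per role/domain in one state (0 marks a resolution gap)."""
        out: dict[str, int] = {}
        for name in list(self.roles) + list(self.domains):
            out[name] = int(state.select(self.expression(name)).size)
        return out


def weighted_quantile(
    values: Sequence[float], weights: Sequence[float], q: float | Sequence[float]
):
    """Weighted quantile with linear interpolation between cumulative steps.

    Each sorted value v_k occupies the cumulative-weight span
    (c_{k-1}, c_k]; the quantile function interpolates linearly between the
    midpoints of consecutive spans, so two equal-weight values 1 and 3 give
    a median of 2 and a single value is every quantile of itself.
    """
    v = np.asarray(values, dtype=float)
    w = _normalize_weights(weights)
    if v.shape != w.shape:
        raise ValidationError("values and weights must have equal length")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    knots = np.cumsum(w) - 0.5 * w
    result = np.interp(q, knots, v)
    return float(result) if np.isscalar(q) else result


@dataclass
class WeightedScalarDistribution:
    """Scalar values with fractional weights and a unit tag."""

    values: np.ndarray
    weights: np.ndarray
    unit: str
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = _normalize_weights(self.weights)
        if self.values.shape != self.weights.shape:
            raise ValidationError("values and weights must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("distribution values must be finite")

    def quantile(self, q):
        return weighted_quantile(self.values, self.weights, q)

    @property
    def median(self) -> float:
        return self.quantile(0.5)

    @property
    def q1(self) -> float:
        return self.quantile(0.25)

    @property
    def q3(self) -> float:
        return self.quantile(0.75)

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def min(self) -> float:
        return float(self.values.min())

    @property
    def max(self) -> float:
        return float(self.values.max())

    def scaled(self, factor: float, unit: str) -> "WeightedScalarDistribution":
        return WeightedScalarDistribution(
            self.values * factor, self.weights, unit, name=self.name
        )


# ---------------------------------------------------------------------------
# PDB / weight-table reading
# ---------------------------------------------------------------------------


def _state_from_model(model: gemmi.Model, label: str) -> StructureState:
    serial, chains, resids, resnames, atomnames, elements = [], [], [], [], [], []
    coords = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                serial.append(atom.serial)
                chains.append(chain.name)
                resids.append(residue.seqid.num)
                resnames.append(residue.name)
                atomnames.append(atom.name)
                elements.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not coords:
        raise ParseError(f"no atoms in model {label!r}")
    return StructureState(
        serial=np.array(serial, dtype=int),
        chain_ids=np.array(chains),
        res_ids=np.array(resids, dtype=int),
        res_names=np.array(resnames),
        atom_names=np.array(atomnames),
        coords=np.array(coords, dtype=float),
        label=label,
        elements=np.array(elements),
    )


def _read_pdb_states(path: str | Path) -> list[StructureState]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"PDB file not found: {path}")
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi raises RuntimeError
        raise ParseError(f"cannot parse PDB {path}: {exc}") from exc
    if len(structure) == 0:
        raise ParseError(f"no models in PDB {path}")
    states = []
    multi = len(structure) > 1
    for model in structure:
        label = str(model.num) if multi else path.stem
        states.append(_state_from_model(model, label))
    return states


def read_weight_table(source) -> list[tuple[str, float]]:
    """Parse a (label, weight) table.

    Accepts a file path, a file-like object, or an inline iterable of
    ``(label, weight)`` pairs. The on-disk dialect is two columns separated
    by tab or comma (whitespace also tolerated), with ``#`` comments.
    Weights may be raw; normalization happens in :func:`read_multistate`.
    """
    if isinstance(source, (list, tuple)):
        return [(str(label), float(w)) for label, w in source]
    if isinstance(source, (str, Path)):
        with open(source, "r") as fh:
            return read_weight_table(fh)
    rows: list[tuple[str, float]] = []
    for lineno, line in enumerate(source, start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = re.split(r"[,\t]", line) if ("," in line or "\t" in line) else line.split()
        if len(parts) != 2:
            raise ParseError(f"weight table line {lineno}: expected 2 columns, got {len(parts)}")
        label, raw = parts[0].strip(), parts[1].strip()
        try:
            w = float(raw)
        except ValueError as exc:
            raise ParseError(f"weight table line {lineno}: non-numeric weight {raw!r}") from exc
        rows.append((label, w))
    if not rows:
        raise ParseError("weight table is empty")
    return rows


def read_multistate(structure_paths, weight_table) -> WeightedEnsemble:
    """Read a weighted multistate ensemble.

    Parameters
    ----------
    structure_paths : one path (possibly multi-model PDB) or a list of
        single-state PDB paths
    weight_table : path, file-like, or inline ``[(label, weight), ...]``;
        one row per state. For a multi-model PDB the labels are the model
        numbers; for a path list they are the file stems.

    States are returned in weight-table order and weights renormalized to
    sum to one.
    """
    rows = read_weight_table(weight_table)
    if any(w < 0 for _, w in rows):
        raise ValidationError("negative weight in weight table")

    if isinstance(structure_paths, (str, Path)):
        states = _read_pdb_states(structure_paths)
    else:
        states = []
        for p in structure_paths:
            parsed = _read_pdb_states(p)
            if len(parsed) != 1:
                raise StructuralError(
                    f"{p}: expected a single-model PDB in list mode, got {len(parsed)} models"
                )
            states.extend(parsed)

    if len(states) != len(rows):
        raise StructuralError(
            f"{len(states)} states but {len(rows)} weight rows"
        )
    by_label = {s.label: s for s in states}
    if len(by_label) != len(states):
        raise StructuralError("duplicate state labels")
    missing = [label for label, _ in rows if label not in by_label]
    if missing:
        raise StructuralError(
            "weight-table labels not found among states: " + ", ".join(missing)
        )
    ordered = [by_label[label] for label, _ in rows]
    return WeightedEnsemble(ordered, np.array([w for _, w in rows]))


def write_multistate(
    ensemble: WeightedEnsemble, pdb_path: str | Path, weights_path: str | Path
) -> None:
    """Write an ensemble as one multi-model PDB plus a weight TSV.

    Model numbers run 1..n in ensemble order; the weight table keys rows by
    model number so :func:`read_multistate` round-trips the ensemble.
    """
    structure = gemmi.Structure()
    structure.name = "ensemble"
    for i, state in enumerate(ensemble.states, start=1):
        model = gemmi.Model(i)
        for chain_name in pd.unique(state.chain_ids):
            chain = gemmi.Chain(str(chain_name))
            sel = np.flatnonzero(state.chain_ids == chain_name)
            for j in sel:
                residue = None
                if chain and chain[-1].seqid.num == int(state.res_ids[j]):
                    residue = chain[-1]
                else:
                    residue = gemmi.Residue()
                    residue.name = str(state.res_names[j])
                    residue.seqid = gemmi.SeqId(int(state.res_ids[j]), " ")
                    chain.add_residue(residue)
                    residue = chain[-1]
                atom = gemmi.Atom()
                atom.name = str(state.atom_names[j])
                atom.serial = int(state.serial[j])
                if state.elements is not None:
                    atom.element = gemmi.Element(str(state.elements[j]))
                x, y, z = state.coords[j]
                atom.pos = gemmi.Position(float(x), float(y), float(z))
                residue.add_atom(atom)
            model.add_chain(chain)
        structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(pdb_path))

    # a single-model file reads back labeled by its stem, not a model number
    labels = (
        [Path(pdb_path).stem]
        if len(ensemble) == 1
        else [str(i) for i in range(1, len(ensemble) + 1)]
    )
    with open(weights_path, "w") as fh:
        fh.write("# model\tweight\n")
        for label, w in zip(labels, ensemble.weights):
            fh.write(f"{label}\t{w:.12g}\n")


# ---------------------------------------------------------------------------
# annotation config
# ---------------------------------------------------------------------------


def parse_annotation(config) -> EnsembleAnnotation:
    """Parse an annotation config (YAML path, file-like, or mapping).

    Layout::

        roles:
          paratope_tip_1: "B:6:CA"
          ...
        domains:
          binder_1: "B"
    """
    if isinstance(config, Mapping):
        data = dict(config)
    else:
        if isinstance(config, (str, Path)):
            with open(config, "r") as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(config)
    if not isinstance(data, Mapping) or "roles" not in data:
        raise ValidationError("annotation config must contain a 'roles' mapping")
    roles = {str(k): str(v) for k, v in dict(data["roles"]).items()}
    domains = {str(k): str(v) for k, v in dict(data.get("domains") or {}).items()}
    for name, expr in {**roles, **domains}.items():
        for term in expr.split(","):
            if term.strip() and _TERM_RE.match(term.strip()) is None:
                raise ValidationError(f"selection {name!r}: malformed term {term.strip()!r}")
    return EnsembleAnnotation(roles=roles, domains=domains)


def serialize_annotation(annotation: EnsembleAnnotation, path: str | Path | None = None) -> str:
    """Serialize an annotation back to its YAML config form."""
    data = {"roles": dict(annotation.roles), "domains": dict(annotation.domains)}
    text = yaml.safe_dump(data, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# SAXS profiles
# ---------------------------------------------------------------------------

DEFAULT_SIGMA_FRACTION = 0.03


def read_saxs_profile(path, sigma_fraction: float = DEFAULT_SIGMA_FRACTION):
    """Read a 3-column (q, I[, sigma]) text curve into a SAXSProfile.

    Comment lines (``#``) and blank lines are tolerated. Rows are sorted by
    q if necessary (with a warning); a missing sigma column is imputed as
    ``sigma_fraction * I``.
    """
    from .saxs_analysis import SAXSProfile  # local import avoids a cycle

    rows = []
    if isinstance(path, (str, Path)):
        fh = open(path, "r")
        close = True
    else:
        fh, close = path, False
    try:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) not in (2, 3):
                raise ParseError(f"line {lineno}: expected 2 or 3 columns")
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric value") from exc
    finally:
        if close:
            fh.close()
    if len(rows) < 5:
        raise ParseError(f"need at least 5 data rows, got {len(rows)}")
    width = max(len(r) for r in rows)
    data = np.array([r + [np.nan] * (width - len(r)) for r in rows], dtype=float)
    q, intensity = data[:, 0], data[:, 1]
    if np.all(intensity <= 0):
        raise ValidationError("all intensities are non-positive")
    sigma = data[:, 2] if width == 3 and not np.any(np.isnan(data[:, 2])) else None
    if np.any(np.diff(q) <= 0):
        warnings.warn("q values not strictly increasing; sorting", stacklevel=2)
        order = np.argsort(q, kind="stable")
        q, intensity = q[order], intensity[order]
        if sigma is not None:
            sigma = sigma[order]
    if sigma is None:
        sigma = sigma_fraction * np.abs(intensity)
    return SAXSProfile(q=q, intensity=intensity, sigma=sigma)


def write_saxs_profile(profile, path) -> None:
    """Write a profile as 3-column whitespace-separated text."""
    with open(path, "w") as fh:
        fh.write("# q intensity sigma\n")
        for q, i, s in zip(profile.q, profile.intensity, profile.sigma):
            fh.write(f"{q:.12e} {i:.12e} {s:.12e}\n")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["name", "unit", "n", "median", "q1", "q3", "min", "max"]


def write_distribution_report(
    dists: Sequence[WeightedScalarDistribution], path: str | Path | None = None
) -> pd.DataFrame:
    """Tabulate weighted summary statistics, one row per distribution.

    Returns the DataFrame; writes CSV when a path is given. Column order is
    fixed so reports are byte-comparable across runs.
    """
    if len(dists) == 0:
        raise ValidationError("no distributions to report")
    rows = []
    for d in dists:
        rows.append(
            {
                "name": d.name,
                "unit": d.unit,
                "n": len(d.values),
                "median": d.median,
                "q1": d.q1,
                "q3": d.q3,
                "min": d.min,
                "max": d.max,
            }
        )
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if path is not None:
        frame.to_csv(path, index=False)
    return frame
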