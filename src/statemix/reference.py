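"""Cell-state-resolved reference profiles built from single-cell counts.

A reference profile is a gene × state matrix ``A`` whose column ``s`` is the
probability distribution over genes of a read emitted by cell state ``s``
(each column sums to 1), together with a many-to-one map from cell states to
cell types.  States capture distinct expression programs within a type; the
deconvolution runs at state resolution and aggregates to types afterwards.

Profiles are estimated by maximum likelihood: pool the raw (non-log) counts
of all cells carrying the same state label and normalise.  A small
pseudocount keeps every gene representable in every state so that downstream
mixture denominators never vanish.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateStateError,
    FormatError,
    InputError,
    LabelingError,
    ParameterError,
)

DEFAULT_PSEUDOCOUNT = 1e-8


@dataclass
class SingleCellCounts:
    """Raw single-cell count matrix with per-cell type (and state) labels.

    Parameters
    ----------
    counts
        Gene × cell matrix of raw, non-log-transformed counts.
    gene_ids
        One identifier per row of ``counts``.
    cell_type_labels
        One cell-type label per column of ``counts``.
    cell_state_labels
        Optional finer-grained labels; each state label must pair with
        exactly one type label across all cells.
    cell_ids
        Optional barcodes; generated if absent.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_type_labels: list[str]
    cell_state_labels: list[str] | None = None
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise InputError("counts must be a 2D gene × cell matrix")
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise InputError(
                f"{len(self.gene_ids)} gene ids for {n_genes} count rows"
            )
        if len(self.cell_type_labels) != n_cells:
            raise InputError(
                f"{len(self.cell_type_labels)} type labels for {n_cells} cells"
            )
        if self.cell_state_labels is not None and len(self.cell_state_labels) != n_cells:
            raise InputError(
                f"{len(self.cell_state_labels)} state labels for {n_cells} cells"
            )
        if np.any(self.counts < 0):
            raise InputError("counts must be non-negative")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i}" for i in range(n_cells)]
        elif len(self.cell_ids) != n_cells:
            raise InputError(f"{len(self.cell_ids)} cell ids for {n_cells} cells")
        # every state label must belong to a single type label
        if self.cell_state_labels is not None:
            seen: dict[str, str] = {}
            for st, ty in zip(self.cell_state_labels, self.cell_type_labels):
                if st in seen and seen[st] != ty:
                    raise LabelingError(
                        f"cell state {st!r} appears under types "
                        f"{seen[st]!r} and {ty!r}"
                    )
                seen.setdefault(st, ty)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class ReferenceProfile:
    """Gene × state probability matrix plus the state → type map."""

    A: np.ndarray
    gene_ids: list[str]
    state_ids: list[str]
    state_to_type: dict[str, str]
    type_ids: list[str]
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise InputError("A must be 2D (gene × state)")
        if self.A.shape != (len(self.gene_ids), len(self.state_ids)):
            raise InputError(
                f"A has shape {self.A.shape}, expected "
                f"({len(self.gene_ids)}, {len(self.state_ids)})"
            )
        missing = [s for s in self.state_ids if s not in self.state_to_type]
        if missing:
            raise InputError(f"states without a type mapping: {missing}")

    @property
    def n_states(self) -> int:
        return len(self.state_ids)

    @property
    def n_types(self) -> int:
        return len(self.type_ids)

    def type_index_of_state(self) -> np.ndarray:
        """Integer type index for each state column."""
        lookup = {t: i for i, t in enumerate(self.type_ids)}
        return np.array([lookup[self.state_to_type[s]] for s in self.state_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.gene_ids, columns=self.state_ids)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_reference`."""

    violations: list[str]
    n_types: int
    n_states: int
    states_per_type: dict[str, int]

    @property
    def ok(self) -> bool:
        return not self.violations


def _namespace_state(type_label: str, state_label: str) -> str:
    """Globally unique state id: ``type.state`` unless already redundant."""
    if state_label == type_label or state_label.startswith(type_label + "."):
        return state_label
    return f"{type_label}.{state_label}"


def ref_prepare(
    sc: SingleCellCounts, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> ReferenceProfile:
    """Build a reference profile by pooled maximum-likelihood estimation.

    Counts of all cells sharing a state label are summed gene-wise; each
    pooled column (plus ``pseudocount`` per gene) is normalised to a
    probability distribution.  Genes with zero counts in *every* state are
    dropped (they carry no information and would distort normalisation) and
    recorded in ``dropped_genes``.

    When ``cell_state_labels`` are absent, each cell type is treated as a
    single state.
    """
    if pseudocount < 0:
        raise ParameterError("pseudocount must be non-negative")
    states = (
        sc.cell_state_labels
        if sc.cell_state_labels is not None
        else list(sc.cell_type_labels)
    )
    pairs = sorted({(t, s) for s, t in zip(states, sc.cell_type_labels)})
    state_order = [(t, s) for t, s in pairs]

    n_states = len(state_order)
    pooled = np.zeros((sc.n_genes, n_states))
    col_of = {s: j for j, (_, s) in enumerate(state_order)}
    states_arr = np.asarray(states)
    for s, j in col_of.items():
        pooled[:, j] = sc.counts[:, states_arr == s].sum(axis=1)

    keep = pooled.sum(axis=1) > 0
    dropped = [g for g, k in zip(sc.gene_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} gene(s) with zero counts in every state",
            stacklevel=2,
        )
    pooled = pooled[keep]
    gene_ids = [g for g, k in zip(sc.gene_ids, keep) if k]

    totals = pooled.sum(axis=0)
    if pseudocount == 0 and np.any(totals == 0):
        bad = [s for (_, s), tot in zip(state_order, totals) if tot == 0]
        raise DegenerateStateError(
            f"state(s) {bad} have zero total counts and pseudocount is 0"
        )
    A = pooled + pseudocount
    A = A / A.sum(axis=0, keepdims=True)

    state_ids = [_namespace_state(t, s) for t, s in state_order]
    state_to_type = {sid: t for sid, (t, _) in zip(state_ids, state_order)}
    type_ids = sorted({t for t, _ in state_order})
    return ReferenceProfile(
        A=A,
        gene_ids=gene_ids,
        state_ids=state_ids,
        state_to_type=state_to_type,
        type_ids=type_ids,
        dropped_genes=dropped,
    )


def derive_cell_states(
    sc: SingleCellCounts, states_per_type: int, seed: int = 0
) -> SingleCellCounts:
    """Assign cell-state labels by per-type k-means clustering.

    Cells are library-size normalised (so sequencing depth is not a cluster
    driver), log1p-transformed and partitioned within each cell type into
    ``min(states_per_type, n_cells_of_type)`` clusters.  Deterministic for a
    fixed seed.  With ``states_per_type=1`` the state labels equal the type
    labels.
    """
    from sklearn.cluster import KMeans

    if states_per_type < 1:
        raise ParameterError("states_per_type must be >= 1")
    n_cells = sc.n_cells
    state_labels = [""] * n_cells
    libsize = sc.counts.sum(axis=0)
    target = float(np.median(libsize[libsize > 0])) if np.any(libsize > 0) else 1.0
    scaled = np.zeros_like(sc.counts)
    nz = libsize > 0
    scaled[:, nz] = sc.counts[:, nz] / libsize[nz] * target
    logged = np.log1p(scaled)

    types_arr = np.asarray(sc.cell_type_labels)
    for ty in sorted(set(sc.cell_type_labels)):
        idx = np.flatnonzero(types_arr == ty)
        k = min(states_per_type, idx.size)
        if k == 1:
            for i in idx:
                state_labels[i] = ty
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        assign = km.fit_predict(logged[:, idx].T)
        # relabel clusters deterministically by first occurrence
        remap: dict[int, int] = {}
        for a in assign:
            if a not in remap:
                remap[a] = len(remap) + 1
        for i, a in zip(idx, assign):
            state_labels[i] = f"{ty}.s{remap[a]}"

    return SingleCellCounts(
        counts=sc.counts.copy(),
        gene_ids=list(sc.gene_ids),
        cell_type_labels=list(sc.cell_type_labels),
        cell_state_labels=state_labels,
        cell_ids=list(sc.cell_ids) if sc.cell_ids is not None else None,
    )


def validate_reference(ref: ReferenceProfile, atol: float = 1e-9) -> ValidationReport:
    """Check all reference invariants; violations are reported, not raised."""
    violations: list[str] = []
    if np.any(ref.A < 0):
        violations.append("negative entries in A")
    colsums = ref.A.sum(axis=0)
    bad = np.flatnonzero(np.abs(colsums - 1.0) > atol)
    for j in bad:
        violations.append(
            f"column {ref.state_ids[j]!r} sums to {colsums[j]:.6g}, not 1"
        )
    zero_cols = np.flatnonzero(ref.A.sum(axis=0) == 0)
    for j in zero_cols:
        violations.append(f"column {ref.state_ids[j]!r} is all zero")
    for s in ref.state_ids:
        t = ref.state_to_type.get(s)
        if t is None:
            violations.append(f"state {s!r} has no type mapping")
        elif t not in ref.type_ids:
            violations.append(f"state {s!r} maps to unknown type {t!r}")
    if ref.n_states < ref.n_types:
        violations.append(
            f"fewer states ({ref.n_states}) than types ({ref.n_types})"
        )
    per_type: dict[str, int] = {t: 0 for t in ref.type_ids}
    for s in ref.state_ids:
        t = ref.state_to_type.get(s)
        if t in per_type:
            per_type[t] += 1
    return ValidationReport(
        violations=violations,
        n_types=ref.n_types,
        n_states=ref.n_states,
        states_per_type=per_type,
    )


def write_reference(ref: ReferenceProfile, path: str | Path) -> None:
    """Write a reference as TSV (genes × states) plus a JSON sidecar.

    The sidecar at ``<path>.map.json`` holds the state → type map.
    """
    path = Path(path)
    ref.to_frame().to_csv(path, sep="\t", index_label="gene")
    sidecar = path.with_name(path.name + ".map.json")
    sidecar.write_text(json.dumps(ref.state_to_type, indent=1))


def read_reference(path: str | Path) -> ReferenceProfile:
    """Read a reference written by :func:`write_reference`."""
    path = Path(path)
    sidecar = path.with_name(path.name + ".map.json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    frame = pd.read_csv(path, sep="\t", index_col=0)
    try:
        state_to_type = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unparseable sidecar {sidecar}: {exc}") from exc
    states = [str(c) for c in frame.columns]
    missing = [s for s in states if s not in state_to_type]
    if missing:
        raise FormatError(f"sidecar missing state keys: {missing}")
    extra = [s for s in state_to_type if s not in set(states)]
    if extra:
        raise FormatError(f"sidecar has unknown states: {extra}")
    type_ids = sorted(set(state_to_type.values()))
    return ReferenceProfile(
        A=frame.to_numpy(dtype=float),
        gene_ids=[str(g) for g in frame.index],
        state_ids=states,
        state_to_type={str(k): str(v) for k, v in state_to_type.items()},
        type_ids=type_ids,
    )
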