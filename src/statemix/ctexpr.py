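"""Cell-type-specific expression from the compressed representation.

Storing the full gene × sample × type array Z is the memory bottleneck of
read-assignment deconvolution.  Everything needed to rebuild any slice of Z
is already contained in the fitted state fractions plus the per-gene,
per-sample mixture denominator

    d_{g,n} = sum_s A_{g,s} * theta_{n,s}

(a single gene × sample "scaling matrix").  The reconstruction apportions
each observed bulk value among types by posterior responsibility:

    Z_{g,n,k} = X_{g,n} * (sum_{s in type k} A_{g,s} theta_{n,s}) / d_{g,n}

so summing Z over types returns X exactly (conservation).

The optional second round re-estimates a type-level reference from Z —
either pooled across samples, or with one profile per sample for a declared
malignant type whose expression is patient-specific — and re-deconvolves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateStateError, InputError
from .model import BulkMatrix, DeconvolutionResults, run_deconv
from .reference import DEFAULT_PSEUDOCOUNT, ReferenceProfile


@dataclass
class CompressedZ:
    """Theta plus the 2D scaling matrix; Z slices are rebuilt on demand."""

    theta_state: np.ndarray  # sample × state
    reference: ReferenceProfile
    d: np.ndarray  # gene × sample mixture denominators

    @classmethod
    def from_fit(
        cls, reference: ReferenceProfile, theta_state: np.ndarray
    ) -> "CompressedZ":
        theta_state = np.atleast_2d(np.asarray(theta_state, dtype=float))
        d = reference.A @ theta_state.T
        return cls(theta_state=theta_state, reference=reference, d=d)


@dataclass
class CellTypeExpression:
    """Gene × sample × type array of apportioned bulk expression."""

    Z: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    type_ids: list[str]

    def slice_type(self, cell_type: str) -> np.ndarray:
        try:
            k = self.type_ids.index(cell_type)
        except ValueError:
            raise KeyError(f"unknown cell type {cell_type!r}") from None
        return self.Z[:, :, k]


def reconstruct_Z_ct(
    X: np.ndarray | BulkMatrix, compressed: CompressedZ, cell_type: str
) -> np.ndarray:
    """Gene × sample expression attributed to ``cell_type``."""
    x = X.X if isinstance(X, BulkMatrix) else np.asarray(X, dtype=float)
    ref = compressed.reference
    if cell_type not in ref.type_ids:
        raise KeyError(f"unknown cell type {cell_type!r}")
    if x.shape != compressed.d.shape:
        raise InputError(
            f"bulk shape {x.shape} does not match compressed shape "
            f"{compressed.d.shape}"
        )
    mask = np.array([ref.state_to_type[s] == cell_type for s in ref.state_ids])
    # numerator: per-type share of the mixture density
    num = ref.A[:, mask] @ compressed.theta_state[:, mask].T
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(compressed.d > 0, num / compressed.d, 0.0)
    return np.where(x > 0, x * share, 0.0)


def get_Z_array(
    X: np.ndarray | BulkMatrix, compressed: CompressedZ
) -> CellTypeExpression:
    """Stack :func:`reconstruct_Z_ct` over all types."""
    x = X.X if isinstance(X, BulkMatrix) else np.asarray(X, dtype=float)
    ref = compressed.reference
    slabs = [reconstruct_Z_ct(x, compressed, t) for t in ref.type_ids]
    gene_ids = list(ref.gene_ids)
    sample_ids = (
        list(X.sample_ids)
        if isinstance(X, BulkMatrix)
        else [f"sample{i}" for i in range(x.shape[1])]
    )
    return CellTypeExpression(
        Z=np.stack(slabs, axis=2),
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        type_ids=list(ref.type_ids),
    )


@dataclass
class PerSampleReference:
    """Reference bundle with a sample-specific malignant profile.

    Non-malignant (environment) types share pooled columns; the malignant
    type has one column per sample.
    """

    env_A: np.ndarray  # gene × (K-1) pooled environment profiles
    env_type_ids: list[str]
    malignant_A: np.ndarray  # gene × sample
    malignant_type: str
    gene_ids: list[str]
    sample_ids: list[str]

    @property
    def type_ids(self) -> list[str]:
        return self.env_type_ids + [self.malignant_type]

    def for_sample(self, n: int) -> ReferenceProfile:
        A = np.column_stack([self.env_A, self.malignant_A[:, n]])
        type_ids = self.type_ids
        return ReferenceProfile(
            A=A,
            gene_ids=list(self.gene_ids),
            state_ids=list(type_ids),
            state_to_type={t: t for t in type_ids},
            type_ids=sorted(type_ids),
        )


def update_reference(
    Z: CellTypeExpression,
    mode: str = "pooled",
    malignant: str | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ReferenceProfile | PerSampleReference:
    """Re-estimate a type-level reference from reconstructed expression.

    ``pooled`` sums Z over samples per type and normalises.  In
    ``per_sample_malignant`` mode the named malignant type instead keeps one
    profile per sample, reflecting patient-specific tumour expression, while
    environment types stay pooled.
    """
    if mode not in ("pooled", "per_sample_malignant"):
        raise InputError(f"unknown update mode {mode!r}")
    pooled = Z.Z.sum(axis=1)  # gene × type
    totals = pooled.sum(axis=0)
    if pseudocount == 0 and np.any(totals == 0):
        bad = [t for t, tot in zip(Z.type_ids, totals) if tot == 0]
        raise DegenerateStateError(f"type(s) {bad} have zero total Z mass")
    if mode == "pooled":
        A = pooled + pseudocount
        A = A / A.sum(axis=0, keepdims=True)
        return ReferenceProfile(
            A=A,
            gene_ids=list(Z.gene_ids),
            state_ids=list(Z.type_ids),
            state_to_type={t: t for t in Z.type_ids},
            type_ids=sorted(Z.type_ids),
        )
    if malignant is None or malignant not in Z.type_ids:
        raise KeyError(f"malignant type {malignant!r} not in {Z.type_ids}")
    k_mal = Z.type_ids.index(malignant)
    env_ids = [t for t in Z.type_ids if t != malignant]
    env = pooled[:, [Z.type_ids.index(t) for t in env_ids]] + pseudocount
    env = env / env.sum(axis=0, keepdims=True)
    mal = Z.Z[:, :, k_mal] + pseudocount
    mal_tot = mal.sum(axis=0)
    if np.any(mal_tot == 0):
        raise DegenerateStateError(
            f"malignant type {malignant!r} has zero mass in some sample"
        )
    mal = mal / mal_tot
    return PerSampleReference(
        env_A=env,
        env_type_ids=env_ids,
        malignant_A=mal,
        malignant_type=malignant,
        gene_ids=list(Z.gene_ids),
        sample_ids=list(Z.sample_ids),
    )


def run_deconv_updated(
    bulk: BulkMatrix,
    updated: ReferenceProfile | PerSampleReference,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> DeconvolutionResults:
    """Second-round deconvolution against an updated type-level reference.

    With a :class:`PerSampleReference`, each sample is deconvolved against
    its own malignant column plus the shared environment columns; results
    are re-assembled in the bundle's type order.
    """
    if isinstance(updated, ReferenceProfile):
        return run_deconv(bulk, updated, max_iter=max_iter, tol=tol)
    results = []
    for n in range(bulk.n_samples):
        sub = BulkMatrix(
            X=bulk.X[:, [n]],
            gene_ids=list(bulk.gene_ids),
            sample_ids=[bulk.sample_ids[n]],
        )
        results.append(
            run_deconv(sub, updated.for_sample(n), max_iter=max_iter, tol=tol)
        )
    first = results[0]
    theta_state = np.vstack([r.theta_state for r in results])
    theta_type = np.vstack([r.theta_type for r in results])
    merged = DeconvolutionResults(
        model=first.model,
        theta_state=theta_state,
        theta_type=theta_type,
        n_iter_used=np.concatenate([r.n_iter_used for r in results]),
        converged=np.concatenate([r.converged for r in results]),
        loglik=[r.loglik[0] for r in results],
    )
    merged.sample_ids = list(bulk.sample_ids)
    return merged
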