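"""Fixed-point deconvolution of bulk expression against a state reference.

The generative model is a per-sample multinomial mixture (a topic model:
reads are words, samples are documents, cell states are topics, genes the
vocabulary).  A bulk column ``x`` is modelled as

    x ~ Multinomial(n, A @ theta)

with ``A`` the gene × state reference (columns on the simplex) and ``theta``
the unknown state fractions.  Instead of Gibbs-sampling the latent per-read
state assignments, each iteration computes their conditional *mean* in one
vectorised step — the derandomised update

    theta'_s  ∝  sum_g  x_g * A_{g,s} theta_s / (sum_{s'} A_{g,s'} theta_{s'})

which is exactly EM for the multinomial mixture, so the recorded
log-likelihood is non-decreasing and the fixed point is the MLE that the
sampled posterior mean approaches in the large-count regime.

The public surface is statsmodels-flavoured: build a
:class:`DeconvolutionModel` from a :class:`BulkMatrix` and a
:class:`~statemix.reference.ReferenceProfile`, call :meth:`fit`, inspect the
:class:`DeconvolutionResults`.  ``run_deconv`` is the one-call functional
equivalent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .reference import ReferenceProfile

logger = logging.getLogger(__name__)

#: below this max value a matrix is suspected to be log-scaled
_LOG_SCALE_SUSPECT_MAX = 50.0


@dataclass
class BulkMatrix:
    """Gene × sample bulk expression on a linear (non-log) scale."""

    X: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise InputError("X must be 2D (gene × sample)")
        if self.X.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise InputError(
                f"X has shape {self.X.shape}, expected "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if np.any(self.X < 0):
            raise InputError("bulk matrix must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.gene_ids, columns=self.sample_ids)


def intersect_genes(
    bulk: BulkMatrix, ref: ReferenceProfile
) -> tuple[BulkMatrix, ReferenceProfile]:
    """Restrict bulk and reference to their shared genes, in reference order.

    Reference columns are re-normalised to sum to 1 over the retained genes.
    """
    bulk_pos = {g: i for i, g in enumerate(bulk.gene_ids)}
    shared = [g for g in ref.gene_ids if g in bulk_pos]
    if not shared:
        raise InputError("no shared genes between bulk and reference")
    n_drop_bulk = bulk.n_genes - len(shared)
    n_drop_ref = len(ref.gene_ids) - len(shared)
    if n_drop_bulk or n_drop_ref:
        logger.info(
            "gene intersection: kept %d, dropped %d bulk-only and %d reference-only",
            len(shared), n_drop_bulk, n_drop_ref,
        )
    ref_pos = {g: i for i, g in enumerate(ref.gene_ids)}
    ridx = [ref_pos[g] for g in shared]
    A = ref.A[ridx]
    A = A / A.sum(axis=0, keepdims=True)
    new_ref = ReferenceProfile(
        A=A,
        gene_ids=shared,
        state_ids=list(ref.state_ids),
        state_to_type=dict(ref.state_to_type),
        type_ids=list(ref.type_ids),
    )
    bidx = [bulk_pos[g] for g in shared]
    new_bulk = BulkMatrix(
        X=bulk.X[bidx], gene_ids=shared, sample_ids=list(bulk.sample_ids)
    )
    return new_bulk, new_ref


def em_step(
    x: np.ndarray,
    A: np.ndarray,
    theta: np.ndarray,
    prior_concentration: float = 1.0,
) -> np.ndarray:
    """One derandomised update of the state fractions for one bulk column.

    Computes the expected fraction of reads assigned to each state under the
    current mixture and renormalises.  With ``prior_concentration`` α ≠ 1 the
    update targets the MAP under a symmetric Dirichlet(α) prior instead of
    the MLE (expected counts shifted by α − 1, clipped at zero).
    """
    x = np.asarray(x, dtype=float)
    theta = np.asarray(theta, dtype=float)
    d = A @ theta
    bad = (x > 0) & (d <= 0)
    if np.any(bad):
        raise InputError(
            f"zero mixture denominator at {int(bad.sum())} gene(s) with "
            "positive bulk signal; use a reference pseudocount"
        )
    ratio = np.zeros_like(x)
    nz = x > 0
    ratio[nz] = x[nz] / d[nz]
    expected = theta * (A.T @ ratio)
    if prior_concentration != 1.0:
        expected = np.clip(expected + (prior_concentration - 1.0), 0.0, None)
    total = expected.sum()
    if total == 0:
        return np.full_like(theta, 1.0 / theta.size)
    return expected / total


def aggregate_states(
    theta_state: np.ndarray,
    state_to_type: dict[str, str],
    state_ids: list[str],
    type_ids: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Sum state fractions into type fractions; row sums are preserved."""
    unmapped = [s for s in state_ids if s not in state_to_type]
    if unmapped:
        raise InputError(f"unmapped states: {unmapped}")
    if type_ids is None:
        type_ids = sorted({state_to_type[s] for s in state_ids})
    lookup = {t: i for i, t in enumerate(type_ids)}
    theta_state = np.atleast_2d(np.asarray(theta_state, dtype=float))
    out = np.zeros((theta_state.shape[0], len(type_ids)))
    for j, s in enumerate(state_ids):
        out[:, lookup[state_to_type[s]]] += theta_state[:, j]
    return out, type_ids


class DeconvolutionModel:
    """Multinomial-mixture deconvolution model for a bulk matrix.

    Parameters
    ----------
    bulk
        Gene × sample bulk expression, linear scale (counts, TPM, FPKM).
    reference
        Gene × state reference profile.  Genes are intersected (exact string
        match) and reference columns re-normalised at construction.
    prior_concentration
        Symmetric Dirichlet concentration over states; 1 (default) is the
        flat prior, i.e. plain maximum likelihood.
    """

    def __init__(
        self,
        bulk: BulkMatrix,
        reference: ReferenceProfile,
        prior_concentration: float = 1.0,
    ) -> None:
        if prior_concentration <= 0:
            raise ParameterError("prior_concentration must be > 0")
        x = np.asarray(bulk.X)
        if x.size and 0 < x.max() < _LOG_SCALE_SUSPECT_MAX:
            warnings.warn(
                "bulk matrix maximum is below 50; input may be log-scaled, "
                "but a non-log scale is required",
                stacklevel=2,
            )
        self.bulk, self.reference = intersect_genes(bulk, reference)
        self.prior_concentration = prior_concentration

    def fit(self, max_iter: int = 100, tol: float = 1e-6) -> "DeconvolutionResults":
        """Iterate the fixed-point update per sample until convergence.

        Each sample starts from the uniform state vector and stops when the
        maximum absolute change in theta falls below ``tol`` or after
        ``max_iter`` updates.  Samples are independent; the vectorised sweep
        gives results identical to fitting them one at a time.
        """
        if max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        if tol < 0:
            raise ParameterError("tol must be >= 0")
        A = self.reference.A
        X = self.bulk.X
        n_genes, n_samples = X.shape
        n_states = A.shape[1]

        theta = np.full((n_samples, n_states), 1.0 / n_states)
        n_iter = np.zeros(n_samples, dtype=int)
        converged = np.zeros(n_samples, dtype=bool)
        loglik: list[list[float]] = [[] for _ in range(n_samples)]

        totals = X.sum(axis=0)
        dead = totals == 0
        if np.any(dead):
            logger.warning(
                "%d sample(s) have zero total signal; returning uniform "
                "fractions flagged as not converged", int(dead.sum()),
            )
        active = ~dead

        def _loglik(cols: np.ndarray, th: np.ndarray) -> np.ndarray:
            mix = A @ th.T  # gene × n_active
            xa = X[:, cols]
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(xa > 0, xa * np.log(mix), 0.0)
            return terms.sum(axis=0)

        for _ in range(max_iter):
            cols = np.flatnonzero(active)
            if cols.size == 0:
                break
            th = theta[cols]
            for ll_i, i in zip(_loglik(cols, th), cols):
                loglik[i].append(float(ll_i))
            mix = A @ th.T
            xa = X[:, cols]
            bad = (xa > 0) & (mix <= 0)
            if np.any(bad):
                raise InputError(
                    "zero mixture denominator with positive bulk signal; "
                    "use a reference pseudocount"
                )
            ratio = np.divide(xa, mix, out=np.zeros_like(xa), where=xa > 0)
            expected = th * (A.T @ ratio).T
            if self.prior_concentration != 1.0:
                expected = np.clip(
                    expected + (self.prior_concentration - 1.0), 0.0, None
                )
            row_tot = expected.sum(axis=1, keepdims=True)
            row_tot[row_tot == 0] = 1.0
            new_th = expected / row_tot
            delta = np.abs(new_th - th).max(axis=1)
            theta[cols] = new_th
            n_iter[cols] += 1
            done = delta < tol
            converged[cols[done]] = True
            active[cols[done]] = False

        # final log-likelihood at the returned theta
        cols = np.flatnonzero(~dead)
        if cols.size:
            for ll_i, i in zip(_loglik(cols, theta[cols]), cols):
                loglik[i].append(float(ll_i))

        theta_type, type_ids = aggregate_states(
            theta,
            self.reference.state_to_type,
            self.reference.state_ids,
            self.reference.type_ids,
        )
        return DeconvolutionResults(
            model=self,
            theta_state=theta,
            theta_type=theta_type,
            n_iter_used=n_iter,
            converged=converged,
            loglik=loglik,
        )


class DeconvolutionResults:
    """Fitted fractions plus convergence diagnostics.

    The 3D cell-type-specific expression array is *not* stored; it is
    reconstructable on demand from the compressed representation (theta and
    the per-gene-per-sample mixture denominator) via
    :meth:`reconstruct_expression` / :meth:`expression_array`.
    """

    def __init__(
        self,
        model: DeconvolutionModel,
        theta_state: np.ndarray,
        theta_type: np.ndarray,
        n_iter_used: np.ndarray,
        converged: np.ndarray,
        loglik: list[list[float]],
    ) -> None:
        self.model = model
        self.reference = model.reference
        self.bulk = model.bulk
        self.theta_state = theta_state
        self.theta_type = theta_type
        self.n_iter_used = n_iter_used
        self.converged = converged
        self.loglik = loglik
        self.sample_ids = list(model.bulk.sample_ids)
        self.state_ids = list(model.reference.state_ids)
        self.type_ids = list(model.reference.type_ids)

    # -- tabular views ---------------------------------------------------
    def state_fractions(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.theta_state, index=self.sample_ids, columns=self.state_ids
        )

    def type_fractions(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.theta_type, index=self.sample_ids, columns=self.type_ids
        )

    # -- compressed Z ----------------------------------------------------
    def compressed(self):
        """The 2D scaling matrix (mixture denominators) plus theta."""
        from .ctexpr import CompressedZ

        return CompressedZ.from_fit(self.reference, self.theta_state)

    def reconstruct_expression(self, cell_type: str) -> pd.DataFrame:
        """Gene × sample expression attributed to one cell type."""
        from .ctexpr import reconstruct_Z_ct

        z = reconstruct_Z_ct(self.bulk.X, self.compressed(), cell_type)
        return pd.DataFrame(
            z, index=self.bulk.gene_ids, columns=self.sample_ids
        )

    def expression_array(self):
        """Full gene × sample × type array (memory permitting)."""
        from .ctexpr import get_Z_array

        return get_Z_array(self.bulk.X, self.compressed())

    def update_reference(self, mode: str = "pooled", malignant: str | None = None):
        """Type-level reference re-estimated from the reconstructed Z."""
        from .ctexpr import update_reference

        return update_reference(self.expression_array(), mode=mode, malignant=malignant)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary of the fit."""
        lines = [
            "Deconvolution results",
            "=====================",
            f"samples: {len(self.sample_ids)}   genes: {self.bulk.n_genes}   "
            f"states: {len(self.state_ids)}   types: {len(self.type_ids)}",
            f"converged: {int(self.converged.sum())}/{len(self.sample_ids)}   "
            f"iterations: median {int(np.median(self.n_iter_used))}, "
            f"max {int(self.n_iter_used.max())}",
            "",
            "mean cell-type fractions across samples:",
        ]
        means = self.theta_type.mean(axis=0)
        for t, m in sorted(zip(self.type_ids, means), key=lambda p: -p[1]):
            lines.append(f"  {t:<24s} {m:8.4f}")
        return "\n".join(lines)

    def plot_fractions(self, ax=None):
        """Stacked-bar plot of per-sample cell-type fractions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(max(4, len(self.sample_ids) * 0.3), 4))
        bottom = np.zeros(len(self.sample_ids))
        for k, t in enumerate(self.type_ids):
            ax.bar(self.sample_ids, self.theta_type[:, k], bottom=bottom, label=t)
            bottom += self.theta_type[:, k]
        ax.set_ylabel("fraction")
        ax.legend(fontsize="small")
        ax.tick_params(axis="x", rotation=90)
        return ax


def run_deconv(
    bulk: BulkMatrix,
    ref: ReferenceProfile,
    max_iter: int = 100,
    tol: float = 1e-6,
    prior_concentration: float = 1.0,
) -> DeconvolutionResults:
    """One-call deconvolution: construct the model and fit it."""
    model = DeconvolutionModel(bulk, ref, prior_concentration=prior_concentration)
    return model.fit(max_iter=max_iter, tol=tol)
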