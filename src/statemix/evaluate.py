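"""Scoring estimated fractions against ground truth; reference comparison.

The headline metric is the per-cell-type Pearson correlation across samples
between estimated and true fractions, averaged over types, plus per-type
RMSE.  A simple NNLS regression on type-pooled reference profiles is
included as a sanity baseline for the comparison harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import pearsonr

from .errors import InputError
from .model import BulkMatrix, run_deconv
from .reference import ReferenceProfile


@dataclass
class EvaluationReport:
    """Per-type and overall accuracy of a set of fraction estimates."""

    per_type_pearson: dict[str, float]
    per_type_rmse: dict[str, float]
    mean_pearson: float
    mean_rmse: float
    excluded_types: list[str]
    unmatched_types: list[str]
    n_samples: int
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        types = sorted(self.per_type_pearson)
        return pd.DataFrame(
            {
                "pearson": [self.per_type_pearson[t] for t in types],
                "rmse": [self.per_type_rmse[t] for t in types],
            },
            index=types,
        )

    def to_dict(self) -> dict:
        return {
            "per_type_pearson": self.per_type_pearson,
            "per_type_rmse": self.per_type_rmse,
            "mean_pearson": self.mean_pearson,
            "mean_rmse": self.mean_rmse,
            "excluded_types": self.excluded_types,
            "unmatched_types": self.unmatched_types,
            "n_samples": self.n_samples,
            "metadata": self.metadata,
        }


def evaluate_fractions(
    est: pd.DataFrame, truth: pd.DataFrame, metadata: dict | None = None
) -> EvaluationReport:
    """Score sample × type fraction estimates against the ground truth.

    Types are matched by column id; unmatched types are reported, never
    silently dropped.  A type whose truth column has zero variance has no
    defined correlation: it is excluded from the mean with a warning.
    """
    if not est.index.equals(truth.index):
        if set(est.index) != set(truth.index):
            raise InputError("estimate and truth sample sets differ")
        est = est.loc[truth.index]
    common = [t for t in truth.columns if t in est.columns]
    unmatched = sorted(
        set(truth.columns).symmetric_difference(est.columns)
    )
    if not common:
        raise InputError("no shared cell types between estimate and truth")
    if unmatched:
        warnings.warn(f"types present on one side only: {unmatched}", stacklevel=2)

    pearson: dict[str, float] = {}
    rmse: dict[str, float] = {}
    excluded: list[str] = []
    for t in common:
        e = est[t].to_numpy(dtype=float)
        tr = truth[t].to_numpy(dtype=float)
        rmse[t] = float(np.sqrt(np.mean((e - tr) ** 2)))
        if np.ptp(tr) == 0 or np.ptp(e) == 0:
            excluded.append(t)
            warnings.warn(
                f"type {t!r} has zero variance; correlation undefined",
                stacklevel=2,
            )
            pearson[t] = float("nan")
            continue
        pearson[t] = float(pearsonr(e, tr)[0])
    valid = [pearson[t] for t in common if t not in excluded]
    return EvaluationReport(
        per_type_pearson=pearson,
        per_type_rmse=rmse,
        mean_pearson=float(np.mean(valid)) if valid else float("nan"),
        mean_rmse=float(np.mean([rmse[t] for t in common])),
        excluded_types=excluded,
        unmatched_types=unmatched,
        n_samples=len(truth.index),
        metadata=metadata or {},
    )


def compare_references(
    bulk: BulkMatrix,
    refs: list[ReferenceProfile],
    truth: pd.DataFrame,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[tuple[str, EvaluationReport]]:
    """Deconvolve with each candidate reference and rank by mean Pearson.

    Ties keep input order (stable sort), so identical references rank in the
    order they were given.
    """
    if not refs:
        raise InputError("at least one reference is required")
    if names is None:
        names = [f"ref{i + 1}" for i in range(len(refs))]
    if len(names) != len(refs):
        raise InputError("names and refs length mismatch")
    scored = []
    for name, ref in zip(names, refs):
        res = run_deconv(bulk, ref, max_iter=max_iter, tol=tol)
        report = evaluate_fractions(
            res.type_fractions(), truth, metadata={"reference": name}
        )
        scored.append((name, report))
    key = lambda item: -item[1].mean_pearson  # noqa: E731
    return sorted(scored, key=key)


def nnls_baseline(bulk: BulkMatrix, ref: ReferenceProfile) -> pd.DataFrame:
    """Non-negative least-squares fractions on type-pooled profiles.

    Reference state columns are summed within each type and renormalised;
    each bulk column (scaled to proportions) is regressed on those profiles
    with NNLS and the coefficients normalised to sum 1.
    """
    from .model import intersect_genes

    bulk, ref = intersect_genes(bulk, ref)
    type_ids = list(ref.type_ids)
    B = np.zeros((len(ref.gene_ids), len(type_ids)))
    lookup = {t: i for i, t in enumerate(type_ids)}
    for j, s in enumerate(ref.state_ids):
        B[:, lookup[ref.state_to_type[s]]] += ref.A[:, j]
    B = B / B.sum(axis=0, keepdims=True)

    fractions = np.zeros((bulk.n_samples, len(type_ids)))
    for n in range(bulk.n_samples):
        x = bulk.X[:, n]
        total = x.sum()
        if total == 0:
            raise InputError(f"sample {bulk.sample_ids[n]!r} has zero total signal")
        coef, _ = nnls(B, x / total)
        s = coef.sum()
        fractions[n] = coef / s if s > 0 else 1.0 / len(type_ids)
    return pd.DataFrame(fractions, index=bulk.sample_ids, columns=type_ids)
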