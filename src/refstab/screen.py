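"""Candidate reference-gene screening from an RNA-Seq count matrix.

The screen mirrors how stable transcripts are mined from expression data:
library-size normalization, log2 transform, exclusion of genes silent in
any condition, then ranking by the dispersion of log expression across all
samples (ties broken by the spread of per-condition means, then gene name).
The top-k survivors are flagged as candidate reference genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CountMatrix, IntegrityError, RunConfig

__all__ = [
    "ScreenResult",
    "normalize_counts",
    "zero_expression_filter",
    "screen_candidates",
]

KEPT = "kept"
EXCLUDED_ZERO = "excluded_zero_expression"


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the RNA-Seq stability screen.

    ``table`` is indexed by gene with columns ``status`` (kept /
    excluded_zero_expression), ``score`` (SD of log2 expression across
    samples; NaN for excluded genes), ``cond_range`` (max - min of
    per-condition mean log2 expression), ``rank`` and ``selected``.
    ``condition_means`` holds the per-condition mean log2 expression of the
    kept genes.
    """

    table: pd.DataFrame
    condition_means: pd.DataFrame
    k: int
    normalization: str

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[self.table["status"] == KEPT])

    @property
    def excluded(self) -> list[str]:
        return list(self.table.index[self.table["status"] == EXCLUDED_ZERO])


def normalize_counts(matrix: CountMatrix, method: str = "total") -> pd.DataFrame:
    """Library-size normalization of a count matrix.

    Each sample's counts are divided by a size factor — the library total
    (``method='total'``) or the upper quartile of its nonzero counts
    (``method='uq'``) — and multiplied by the geometric mean of all size
    factors, so the overall scale stays comparable to raw counts.
    """
    counts = matrix.counts.astype(float)
    if method == "total":
        factors = counts.sum(axis=0)
    elif method == "uq":
        factors = {}
        for s in counts.columns:
            nz = counts[s][counts[s] > 0]
            if len(nz) < 4:
                raise IntegrityError(
                    f"sample {s!r} has fewer than 4 nonzero genes; "
                    "upper-quartile normalization is degenerate"
                )
            factors[s] = float(np.percentile(nz, 75))
        factors = pd.Series(factors)
    else:
        raise IntegrityError(f"unknown normalization method {method!r}")
    scale = stats.gmean(factors.to_numpy(dtype=float))
    return counts.div(factors, axis=1) * scale


def zero_expression_filter(matrix: CountMatrix) -> tuple[list[str], list[str]]:
    """Partition genes into (kept, excluded).

    A gene is excluded iff the sum of its raw counts within any single
    condition is zero — i.e. it shows no expression for at least one
    experimental condition.  A zero in one replicate with signal in another
    replicate of the same condition does not exclude.
    """
    kept, excluded = [], []
    by_condition = {
        c: matrix.samples_in(c) for c in matrix.conditions
    }
    for gene in matrix.genes:
        row = matrix.counts.loc[gene]
        if any(row[samples].sum() == 0 for samples in by_condition.values()):
            excluded.append(gene)
        else:
            kept.append(gene)
    return kept, excluded


def screen_candidates(
    matrix: CountMatrix,
    k: int = 4,
    normalization: str = "total",
    config: RunConfig | None = None,
) -> ScreenResult:
    """Rank genes by log-expression stability and select the top k.

    Pipeline: normalize -> log2(x + 1) -> drop genes silent in any
    condition (on raw counts, so the pseudocount never masks absence) ->
    score = SD across all samples of log2 expression (n-1 denominator),
    tie-break by the range of per-condition mean log2 expression, then by
    gene name.  The ``k`` lowest-scoring genes are flagged selected.
    """
    if config is not None:
        k = config.screen_k
        normalization = config.normalization
    if k < 1:
        raise IntegrityError("k must be >= 1")
    norm = normalize_counts(matrix, normalization)
    log_expr = np.log2(norm + 1.0)
    kept, excluded = zero_expression_filter(matrix)
    if k > len(kept):
        warnings.warn(
            f"k={k} exceeds the {len(kept)} genes passing the zero-expression "
            "filter; selecting all of them",
            stacklevel=2,
        )
        k = len(kept)

    cond_means = pd.DataFrame(
        {
            c: log_expr.loc[kept, matrix.samples_in(c)].mean(axis=1)
            for c in matrix.conditions
        }
    )
    score = log_expr.loc[kept].std(axis=1, ddof=1)
    cond_range = cond_means.max(axis=1) - cond_means.min(axis=1)

    order = pd.DataFrame(
        {"score": score, "cond_range": cond_range, "_g": kept}, index=kept
    ).sort_values(["score", "cond_range", "_g"], kind="mergesort")
    rank = pd.Series(np.arange(1, len(order) + 1), index=order.index, dtype=float)

    table = pd.DataFrame(
        index=pd.Index(matrix.genes, name="gene"),
        data={
            "status": [KEPT if g in set(kept) else EXCLUDED_ZERO for g in matrix.genes],
            "score": score.reindex(matrix.genes),
            "cond_range": cond_range.reindex(matrix.genes),
            "rank": rank.reindex(matrix.genes),
            "selected": False,
        },
    )
    table.loc[order.index[:k], "selected"] = True
    return ScreenResult(table, cond_means, k=k, normalization=normalization)
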