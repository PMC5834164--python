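"""Comprehensive ranking: geometric-mean aggregation of per-method ranks.

Each stability method orders the candidate genes; the comprehensive ranking
takes, per gene, the geometric mean of its ranks across methods and sorts
ascending.  Exact geometric-mean ties are broken by the arithmetic mean of
the ranks and then by gene name, and annotated as ties.  This reproduces
the aggregation used by the RefFinder web tool when each method's "weight"
for a gene is its rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import IntegrityError
from .stability import StabilityResult

__all__ = [
    "ranks_from_scores",
    "ranks_from_order",
    "comprehensive_ranking",
    "ComprehensiveRanking",
    "aggregate_across_datasets",
]


def ranks_from_scores(result: StabilityResult | pd.Series) -> pd.Series:
    """Ascending competition ranks ("1223") from a stability statistic.

    A :class:`StabilityResult` that already carries its own rank column
    (geNorm's tied final pair, BestKeeper's correlation tie-break) keeps it;
    otherwise ranks are recomputed from the statistic with exact ties
    sharing the smallest applicable rank.
    """
    if isinstance(result, StabilityResult):
        if "rank" in result.table.columns:
            return result.table["rank"].astype(float)
        scores = result.table["value"]
    else:
        scores = result
    arr = scores.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise IntegrityError("scores must be finite to be ranked")
    ranks = stats.rankdata(arr, method="min").astype(float)
    return pd.Series(ranks, index=scores.index)


def ranks_from_order(
    order: list[str], tied_first_pair: bool = False
) -> pd.Series:
    """Rank vector from an ordered most-to-least-stable gene list.

    With ``tied_first_pair`` the first two genes share rank 1 and the next
    gene takes rank 3 (competition ranking) — the convention under which a
    stepwise-exclusion method reports its inseparable best pair.
    """
    if tied_first_pair:
        ranks = [1, 1] + list(range(3, len(order) + 1))
    else:
        ranks = list(range(1, len(order) + 1))
    return pd.Series(ranks, index=order, dtype=float)


@dataclass(frozen=True)
class ComprehensiveRanking:
    """Geometric-mean aggregated ranking over >= 2 stability methods.

    ``table`` is indexed by gene, ordered best-first, with the per-method
    rank columns, ``geomean``, ``final_rank`` and a ``tie`` annotation.
    """

    table: pd.DataFrame
    methods: tuple[str, ...]

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def final_rank(self, gene: str) -> int:
        return int(self.table.loc[gene, "final_rank"])

    def position(self, gene: str) -> int:
        """1-based position of ``gene`` in the aggregated order."""
        return self.final_rank(gene)

    def top(self, n: int) -> list[str]:
        return list(self.table.index[:n])


def comprehensive_ranking(
    rank_vectors: dict[str, pd.Series],
) -> ComprehensiveRanking:
    """Aggregate per-method rank vectors into the comprehensive ranking.

    Parameters
    ----------
    rank_vectors
        Mapping of method name to a Series of ranks indexed by gene.  All
        vectors must cover exactly the same gene set; at least two methods
        are required.
    """
    if len(rank_vectors) < 2:
        raise IntegrityError("comprehensive ranking needs >= 2 methods")
    methods = list(rank_vectors)
    gene_set = set(rank_vectors[methods[0]].index)
    genes = list(rank_vectors[methods[0]].index)
    for m in methods[1:]:
        if set(rank_vectors[m].index) != gene_set:
            missing = gene_set.symmetric_difference(rank_vectors[m].index)
            raise IntegrityError(
                f"method {m!r} does not cover the same genes; mismatch: "
                f"{sorted(missing)}"
            )
    ranks = pd.DataFrame(
        {m: rank_vectors[m].reindex(genes).astype(float) for m in methods}
    )
    if (ranks <= 0).any().any() or not np.isfinite(ranks.to_numpy()).all():
        raise IntegrityError("ranks must be finite and >= 1")
    # product-then-root keeps exact ties exact (rank products are small
    # integers represented exactly in floats)
    geomean = ranks.prod(axis=1) ** (1.0 / len(methods))
    amean = ranks.mean(axis=1)
    out = ranks.copy()
    out["geomean"] = geomean
    out["_amean"] = amean
    out["_g"] = out.index
    out = out.sort_values(["geomean", "_amean", "_g"], kind="mergesort")
    out["final_rank"] = np.arange(1, len(out) + 1)
    tie = np.zeros(len(out), dtype=bool)
    gm = out["geomean"].to_numpy()
    for i in range(1, len(out)):
        if gm[i] == gm[i - 1]:
            tie[i] = tie[i - 1] = True
    out["tie"] = tie
    out = out.drop(columns=["_amean", "_g"])
    out.index.name = "gene"
    return ComprehensiveRanking(out, tuple(methods))


def aggregate_across_datasets(
    first: ComprehensiveRanking, second: ComprehensiveRanking
) -> pd.DataFrame:
    """Sum two comprehensive rankings over the same genes.

    Used to combine the RNA-Seq based and the qPCR based comprehensive
    rankings into one overall ordering: per gene, the two geometric-mean
    values are summed (final ranks are summed too, for reference) and genes
    are sorted ascending by the summed geometric mean.
    """
    if set(first.genes) != set(second.genes):
        raise IntegrityError("comprehensive rankings cover different gene sets")
    genes = first.genes
    out = pd.DataFrame(
        {
            "geomean_sum": first.table["geomean"].reindex(genes)
            + second.table["geomean"].reindex(genes),
            "final_rank_sum": (
                first.table["final_rank"].reindex(genes)
                + second.table["final_rank"].reindex(genes)
            ).astype(int),
        },
        index=pd.Index(genes, name="gene"),
    )
    out["_g"] = out.index
    out = out.sort_values(["geomean_sum", "final_rank_sum", "_g"], kind="mergesort")
    out = out.drop(columns="_g")
    out["overall_rank"] = np.arange(1, len(out) + 1)
    return out
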