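"""The four candidate-reference-gene stability statistics.

All four methods consume a :class:`~refstab.datamodel.CqTable` and emit a
:class:`StabilityResult` with one statistic and one rank per gene
(rank 1 = most stable):

* geNorm — mean pairwise variation M with iterative exclusion of the worst
  gene; the final two genes cannot be separated and are reported tied.
* comparative ΔCt — mean standard deviation of pairwise Cq differences,
  i.e. geNorm's first pass without the iteration.
* BestKeeper — descriptive: per-gene Cq standard deviation and CV%, plus the
  Pearson correlation of each gene with the BestKeeper index (the per-sample
  geometric mean of all candidates' Cq).
* NormFinder — model-based decomposition of each gene's (log-scale)
  expression into an intergroup bias and an intragroup variance, combined
  into a single stability value.

Amplification efficiencies enter the pairwise kernel as a per-gene rescaling
of Cq by log2(E); the default E = 2 leaves Cq untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CqTable, EfficiencyTable, IntegrityError, RefstabError

__all__ = [
    "StabilityResult",
    "pairwise_sd_matrix",
    "genorm",
    "deltact_stability",
    "bestkeeper",
    "normfinder",
    "cq_spread",
]


@dataclass(frozen=True)
class StabilityResult:
    """Per-gene stability statistic and rank for one method.

    ``table`` is indexed by gene with at least the columns ``value`` (the
    method's statistic, lower = more stable) and ``rank``; methods add their
    own auxiliary columns (CV%, index correlation, exclusion order...).
    """

    method: str
    table: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def value(self, gene: str) -> float:
        return float(self.table.loc[gene, "value"])

    def rank(self, gene: str) -> float:
        return float(self.table.loc[gene, "rank"])

    def ordered(self) -> pd.DataFrame:
        """Rows sorted by rank then gene name (deterministic display order)."""
        out = self.table.assign(_g=self.table.index)
        out = out.sort_values(["rank", "_g"], kind="mergesort")
        return out.drop(columns="_g")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"StabilityResult(method={self.method!r}, genes={len(self.table)})"


def _weighted_cq(table: CqTable, efficiencies: EfficiencyTable | None) -> pd.DataFrame:
    eff = efficiencies or EfficiencyTable()
    weights = pd.Series({g: eff.weight(g) for g in table.genes})
    return table.values.mul(weights, axis=0)


def pairwise_sd_matrix(
    table: CqTable, efficiencies: EfficiencyTable | None = None
) -> pd.DataFrame:
    """Matrix V of pairwise variations between genes.

    ``V[j, k]`` is the standard deviation over samples (n-1 denominator) of
    ``log2(E_j)*Cq_j - log2(E_k)*Cq_k``.  With all efficiencies at 2 this is
    the SD of the plain Cq difference, the quantity shared by geNorm and the
    comparative ΔCt method.  Samples missing either gene are dropped
    pairwise; every pair needs at least 3 complete samples.
    """
    if len(table.genes) < 2:
        raise IntegrityError("pairwise variation needs at least 2 genes")
    x = _weighted_cq(table, efficiencies)
    genes = list(x.index)
    arr = x.to_numpy(dtype=float)
    n = len(genes)
    v = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            diff = arr[j] - arr[k]
            diff = diff[np.isfinite(diff)]
            if diff.size < 3:
                raise IntegrityError(
                    f"fewer than 3 complete samples for gene pair "
                    f"({genes[j]!r}, {genes[k]!r})"
                )
            v[j, k] = v[k, j] = float(np.std(diff, ddof=1))
    return pd.DataFrame(v, index=genes, columns=genes)


def deltact_stability(
    table: CqTable, efficiencies: EfficiencyTable | None = None
) -> StabilityResult:
    """Comparative ΔCt method: mean pairwise SD, no iteration.

    Ties in the statistic receive fractional (average) ranks.
    """
    v = pairwise_sd_matrix(table, efficiencies)
    g = len(v)
    mean_sd = v.sum(axis=1) / (g - 1)
    ranks = pd.Series(
        stats.rankdata(mean_sd.to_numpy(), method="average"), index=mean_sd.index
    )
    out = pd.DataFrame({"value": mean_sd, "rank": ranks})
    out.index.name = "gene"
    return StabilityResult("delta_ct", out)


def genorm(
    table: CqTable, efficiencies: EfficiencyTable | None = None
) -> StabilityResult:
    """geNorm expression-stability measure M with stepwise exclusion.

    M_j is the mean pairwise variation of gene j with every other gene in
    the *current* candidate set.  The gene with the highest M is removed and
    M recomputed until two genes remain; those two are inseparable by the
    method and share rank 1, the next gene takes rank 3 (competition
    ranking).  An exclusion tie removes the alphabetically last gene.
    """
    genes = list(table.genes)
    if len(genes) < 3:
        raise IntegrityError("geNorm ranking needs at least 3 genes")
    v = pairwise_sd_matrix(table, efficiencies)

    remaining = list(genes)
    exclusion_order: list[str] = []  # first excluded = least stable
    m_at_exclusion: dict[str, float] = {}
    while len(remaining) > 2:
        sub = v.loc[remaining, remaining]
        m = sub.sum(axis=1) / (len(remaining) - 1)
        worst_value = m.max()
        tied = sorted(m.index[np.isclose(m, worst_value, rtol=0, atol=0)])
        worst = tied[-1]  # alphabetically last among exact ties
        exclusion_order.append(worst)
        m_at_exclusion[worst] = float(m[worst])
        remaining.remove(worst)
    final_pair = sorted(remaining)
    final_m = float(v.loc[final_pair[0], final_pair[1]])
    for gene in final_pair:
        m_at_exclusion[gene] = final_m

    rank: dict[str, int] = {}
    for gene in final_pair:
        rank[gene] = 1
    for i, gene in enumerate(reversed(exclusion_order)):
        rank[gene] = 3 + i

    out = pd.DataFrame(
        {
            "value": [m_at_exclusion[g] for g in genes],
            "rank": [rank[g] for g in genes],
            "excluded_step": [
                exclusion_order.index(g) + 1 if g in exclusion_order else 0
                for g in genes
            ],
            "tied_pair": [g in final_pair for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    return StabilityResult("genorm", out)


def bestkeeper(table: CqTable) -> StabilityResult:
    """BestKeeper descriptive statistics and index correlation.

    Per gene: SD of raw Cq about the arithmetic mean (n-1 denominator) and
    CV% = 100*SD/mean.  The BestKeeper index is the per-sample geometric
    mean over genes of Cq; each gene's Pearson r with the index is reported.
    Genes are ranked by SD ascending, ties broken by higher r then name.
    Samples with any missing value are dropped listwise so that the index is
    defined over a common sample set.
    """
    values = table.values
    if (values.to_numpy() <= 0)[~np.isnan(values.to_numpy())].any():
        raise IntegrityError("BestKeeper requires positive Cq values")
    complete = values.dropna(axis=1, how="any")
    if complete.shape[1] < 3:
        raise IntegrityError("BestKeeper needs >= 3 complete samples")
    arr = complete.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    cv = 100.0 * sd / mean
    index = stats.gmean(arr, axis=0)
    if len(table.genes) == 1:
        r = np.array([1.0])
    else:
        with np.errstate(invalid="ignore"):
            r = np.array(
                [
                    1.0 if np.std(row) == 0 or np.std(index) == 0
                    else float(np.corrcoef(row, index)[0, 1])
                    for row in arr
                ]
            )
    out = pd.DataFrame(
        {"value": sd, "cv_percent": cv, "index_r": r},
        index=pd.Index(table.genes, name="gene"),
    )
    # deterministic order: SD asc, r desc, gene name
    order = out.assign(_g=out.index).sort_values(
        ["value", "index_r", "_g"], ascending=[True, False, True], kind="mergesort"
    )
    rank = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    # exact ties on (SD, r) share a competition rank
    key = list(zip(order["value"], order["index_r"]))
    for i in range(1, len(key)):
        if key[i] == key[i - 1]:
            rank.iloc[i] = rank.iloc[i - 1]
    out["rank"] = rank.reindex(out.index)
    out["bk_index_mean"] = float(np.mean(index))
    return StabilityResult("bestkeeper", out[["value", "rank", "cv_percent", "index_r"]])


def normfinder(
    table: CqTable, groups: dict[str, str] | None = None
) -> StabilityResult:
    """NormFinder-style bias + variance stability value.

    Expression is taken as y = -Cq (log2 scale up to a constant, E = 2).
    Per sample, the across-gene mean is subtracted (removing the loading
    offset); for each gene and condition group the residuals yield an
    intergroup bias d (deviation of the group mean from the gene's overall
    group-mean average, summing to zero per gene) and an intragroup SD s.
    The stability value is the mean over groups of ``|d| + s``; lower is
    more stable.  This is the simplified form of the variance-decomposition
    estimator; exact small-sample corrections are not applied, so only the
    ranking — not the absolute scale — should be compared across tools.
    """
    if len(table.genes) < 3:
        raise IntegrityError("NormFinder needs at least 3 genes")
    values = table.values.dropna(axis=1, how="any")
    meta = table.meta.loc[values.columns]
    if groups is None:
        groups = {s: meta.loc[s, "condition"] for s in values.columns}
    group_labels = pd.Series({s: groups[s] for s in values.columns})
    sizes = group_labels.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise IntegrityError(
            f"NormFinder groups need >= 2 samples; too small: {list(small.index)}"
        )
    if sizes.size == 1:
        warnings.warn(
            "single group: intergroup bias is identically zero and the "
            "stability value reduces to the mean within-group SD",
            stacklevel=2,
        )
    y = -values  # log2 expression up to an additive constant
    u = y - y.mean(axis=0)  # remove per-sample (loading) effect

    genes = list(values.index)
    group_names = list(dict.fromkeys(group_labels))
    d = pd.DataFrame(index=genes, columns=group_names, dtype=float)
    s = pd.DataFrame(index=genes, columns=group_names, dtype=float)
    for gname in group_names:
        cols = group_labels.index[group_labels == gname]
        sub = u[cols]
        d[gname] = sub.mean(axis=1)
        s[gname] = sub.std(axis=1, ddof=1)
    d = d.sub(d.mean(axis=1), axis=0)  # deviations from the gene's group-mean average
    rho = (d.abs() + s).mean(axis=1)
    ranks = pd.Series(
        stats.rankdata(rho.to_numpy(), method="average"), index=rho.index
    )
    out = pd.DataFrame(
        {
            "value": rho,
            "rank": ranks,
            "max_abs_bias": d.abs().max(axis=1),
            "mean_intragroup_sd": s.mean(axis=1),
        }
    )
    out.index.name = "gene"
    result = StabilityResult("normfinder", out)
    # expose the full decomposition for diagnostics
    object.__setattr__(result, "bias", d)
    object.__setattr__(result, "intragroup_sd", s)
    return result


def cq_spread(table: CqTable) -> pd.DataFrame:
    """Box-plot style five-number summary of raw Cq values per gene.

    Quartiles use linear interpolation; whiskers extend to the most extreme
    observation within 1.5 * IQR of the quartiles; points beyond are listed
    as outliers.  ``range`` is the plain max - min span in cycles, the
    quantity a raw Cq-spread comparison ranks genes by.
    """
    rows = []
    for gene in table.genes:
        vals = table.values.loc[gene].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            raise IntegrityError(f"gene {gene!r} has no Cq values")
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        outliers = np.sort(vals[(vals < lo_fence) | (vals > hi_fence)])
        rows.append(
            {
                "gene": gene,
                "n": vals.size,
                "min": vals.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": vals.max(),
                "whisker_low": inside.min(),
                "whisker_high": inside.max(),
                "range": vals.max() - vals.min(),
                "outliers": ";".join(f"{o:.6g}" for o in outliers),
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    return out
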