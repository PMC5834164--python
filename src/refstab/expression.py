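"""Relative quantification by 2^-ddCt with a multi-gene reference index.

Workflow (per target gene):

1. reference index per sample = arithmetic mean of the reference genes' Cq
   (the Cq-scale equivalent of a geometric mean of linear quantities at
   perfect efficiency);
2. dCt = Cq_target - index, per replicate sample;
3. ddCt = dCt - mean dCt over the calibrator condition's replicates;
4. fold change = 2^-ddCt per replicate; per condition, the mean and SEM of
   replicate fold changes are reported.

Significance between conditions is assessed on the replicate-level dCt
values (log scale, closer to homoscedastic normal than fold changes) with a
one-way ANOVA followed by Tukey's HSD at level alpha, summarised as a
compact letter display: two conditions share a letter iff they are not
significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CqTable, EfficiencyTable, IntegrityError

__all__ = [
    "reference_index",
    "delta_delta_ct",
    "tukey_letters",
    "ExpressionResult",
]


def reference_index(table: CqTable, refs: list[str]) -> pd.Series:
    """Per-sample reference Cq: arithmetic mean of the reference genes."""
    refs = list(refs)
    if not refs:
        raise IntegrityError("reference gene set is empty")
    missing = [g for g in refs if g not in table.values.index]
    if missing:
        raise IntegrityError(f"reference genes absent from table: {missing}")
    sub = table.values.loc[refs]
    if sub.isna().any().any():
        gene = sub.index[sub.isna().any(axis=1)][0]
        sample = sub.columns[sub.isna().any(axis=0)][0]
        raise IntegrityError(
            f"missing reference Cq for gene {gene!r} in sample {sample!r}"
        )
    return sub.mean(axis=0)


@dataclass
class ExpressionResult:
    """Per-condition fold changes for each target gene.

    ``summary`` is indexed by (gene, condition) with mean fold change, SEM
    and (after :func:`tukey_letters`) the significance letters;
    ``replicates`` keeps the replicate-level dCt, ddCt and fold changes.
    """

    summary: pd.DataFrame
    replicates: pd.DataFrame
    calibrator: str
    references: tuple[str, ...]
    targets: tuple[str, ...]
    conditions: tuple[str, ...]
    alpha: float = 0.05
    anova: pd.DataFrame | None = None

    def fold_change(self, gene: str, condition: str) -> float:
        return float(self.summary.loc[(gene, condition), "fold_change"])

    def letters(self, gene: str) -> dict[str, str]:
        sub = self.summary.loc[gene]
        return {c: str(sub.loc[c, "letters"]) for c in sub.index}

    def separated(self, gene: str, cond_a: str, cond_b: str) -> bool:
        """True iff the two conditions share no significance letter."""
        la = set(self.summary.loc[(gene, cond_a), "letters"])
        lb = set(self.summary.loc[(gene, cond_b), "letters"])
        return not (la & lb)


def delta_delta_ct(
    table: CqTable,
    targets: list[str],
    refs: list[str],
    calibrator: str,
    efficiencies: EfficiencyTable | None = None,
    efficiency_corrected: bool = False,
) -> ExpressionResult:
    """Relative expression of ``targets`` vs ``refs``, calibrated.

    With ``efficiency_corrected`` the per-replicate ratio uses each gene's
    own amplification factor E instead of 2 (the classic assumption):
    ratio = E_t^-ddCt_t / geometric mean over refs of E_r^-ddCt_r.
    """
    targets, refs = list(targets), list(refs)
    if set(targets) & set(refs):
        raise IntegrityError("target genes must be disjoint from references")
    missing = [g for g in targets if g not in table.values.index]
    if missing:
        raise IntegrityError(f"target genes absent from table: {missing}")
    if calibrator not in table.conditions:
        raise IntegrityError(f"calibrator condition {calibrator!r} absent")
    cal_samples = table.samples_in(calibrator)

    rep_rows = []
    for gene in targets:
        cq_t = table.values.loc[gene]
        if cq_t.isna().any():
            bad = cq_t.index[cq_t.isna()][0]
            raise IntegrityError(f"missing Cq for target {gene!r} in {bad!r}")
        dct = cq_t - reference_index(table, refs)
        ddct = dct - dct[cal_samples].mean()
        if efficiency_corrected:
            # Pfaffl-style ratio on each gene's own amplification base:
            # log2 FC = w_t*(calmean_t - Cq_t) - mean_r w_r*(calmean_r - Cq_r)
            eff = efficiencies or EfficiencyTable()
            log_fc = eff.weight(gene) * (cq_t[cal_samples].mean() - cq_t)
            for r in refs:
                cq_r = table.values.loc[r]
                log_fc = log_fc - eff.weight(r) * (
                    cq_r[cal_samples].mean() - cq_r
                ) / len(refs)
            fc = np.exp2(log_fc)
        else:
            fc = np.exp2(-ddct)
        for s in table.samples:
            rep_rows.append(
                {
                    "gene": gene,
                    "sample": s,
                    "condition": table.condition_of(s),
                    "replicate": table.replicate_of(s),
                    "dct": float(dct[s]),
                    "ddct": float(ddct[s]),
                    "fold_change": float(fc[s]),
                }
            )
    replicates = pd.DataFrame(rep_rows)

    grouped = replicates.groupby(["gene", "condition"], sort=False)
    # primary fold change is 2^(-mean ddCt), the geometric mean of the
    # replicate fold changes: exactly 1 at the calibrator by construction;
    # the arithmetic mean is kept alongside, SEM is on replicate FCs
    summary = grouped.agg(
        fold_change=("fold_change", lambda v: float(np.exp(np.mean(np.log(v))))),
        fold_change_amean=("fold_change", "mean"),
        sem=(
            "fold_change",
            lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
        ),
        n=("fold_change", "count"),
    )
    summary["letters"] = ""
    conditions = tuple(table.conditions)
    return ExpressionResult(
        summary=summary,
        replicates=replicates,
        calibrator=calibrator,
        references=tuple(refs),
        targets=tuple(targets),
        conditions=conditions,
        anova=None,
    )


def _compact_letters(
    groups: list[str], significant: set[tuple[str, str]], order: list[str]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``order`` fixes letter assignment: the first group of ``order`` carries
    letter 'a'.  Two groups share a letter iff their pair is not in
    ``significant``.
    """
    columns: list[set[str]] = [set(groups)]
    for a, b in sorted(significant):
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop any column contained in another (and exact duplicates)
        columns = []
        for i, col in enumerate(new_cols):
            redundant = any(
                col < other or (col == other and j < i)
                for j, other in enumerate(new_cols)
                if j != i
            )
            if not redundant:
                columns.append(col)
    # deterministic letter order: columns sorted by the best group they hold
    pos = {g: i for i, g in enumerate(order)}
    columns.sort(key=lambda col: min(pos[g] for g in col) if col else len(order))
    letters = {g: "" for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for i, col in enumerate(c for c in columns if c):
        letter = alphabet[i % 26] * (1 + i // 26)
        for g in col:
            letters[g] += letter
    return letters


def tukey_letters(result: ExpressionResult, alpha: float | None = None) -> ExpressionResult:
    """One-way ANOVA + Tukey HSD on replicate dCt, per target gene.

    Letters are assigned in order of decreasing mean fold change, so the
    condition with the highest expression carries 'a'.  Updates ``result``
    in place (filling the ``letters`` column) and returns it.
    """
    alpha = result.alpha if alpha is None else alpha
    anova_rows = []
    for gene in result.targets:
        sub = result.replicates[result.replicates["gene"] == gene]
        conds = [c for c in result.conditions if c in set(sub["condition"])]
        groups = [
            sub.loc[sub["condition"] == c, "dct"].to_numpy(dtype=float)
            for c in conds
        ]
        if len(conds) < 2 or min(len(g) for g in groups) < 2:
            raise IntegrityError(
                "Tukey letters need >= 2 conditions with >= 2 replicates each"
            )
        means = {c: float(np.mean(g)) for c, g in zip(conds, groups)}
        pooled_var = float(
            np.sum([(len(g) - 1) * np.var(g, ddof=1) for g in groups])
            / np.sum([len(g) - 1 for g in groups])
        )
        significant: set[tuple[str, str]] = set()
        if pooled_var <= 1e-24:
            # zero within-group variance: every pair of unequal means differs
            f_stat, p_val = np.inf, 0.0
            for i in range(len(conds)):
                for j in range(i + 1, len(conds)):
                    if means[conds[i]] != means[conds[j]]:
                        significant.add(tuple(sorted((conds[i], conds[j]))))
            if not significant:
                f_stat, p_val = 0.0, 1.0
        else:
            f_stat, p_val = stats.f_oneway(*groups)
            hsd = stats.tukey_hsd(*groups)
            for i in range(len(conds)):
                for j in range(i + 1, len(conds)):
                    if hsd.pvalue[i, j] < alpha:
                        significant.add(tuple(sorted((conds[i], conds[j]))))
        anova_rows.append(
            {"gene": gene, "F": float(f_stat), "p": float(p_val),
             "n_significant_pairs": len(significant)}
        )
        # letter order: highest mean fold change first
        fc_means = {
            c: float(result.summary.loc[(gene, c), "fold_change"]) for c in conds
        }
        order = sorted(conds, key=lambda c: (-fc_means[c], c))
        letters = _compact_letters(conds, significant, order)
        for c in conds:
            result.summary.loc[(gene, c), "letters"] = letters[c]
    result.anova = pd.DataFrame(anova_rows).set_index("gene")
    result.alpha = alpha
    return result
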