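"""Model/Results layer tying the stability statistics together.

Two model classes in the fit-and-summarise idiom:

* :class:`ReferenceGeneStability` — built from a Cq table; ``fit()`` runs
  the four stability methods and the geometric-mean comprehensive ranking
  and returns a :class:`ReferenceGeneStabilityResults` with the per-method
  tables, the aggregated ranking, the raw Cq spread diagnostics and a
  ``summary()`` text table.
* :class:`RelativeExpression` — built from a Cq table plus target genes, a
  reference set and a calibrator condition; ``fit()`` computes 2^-ddCt
  fold changes with SEMs and Tukey compact-letter significance groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import ComprehensiveRanking, comprehensive_ranking, ranks_from_scores
from .datamodel import CqTable, EfficiencyTable, IntegrityError
from .expression import ExpressionResult, delta_delta_ct, tukey_letters
from .stability import (
    StabilityResult,
    bestkeeper,
    cq_spread,
    deltact_stability,
    genorm,
    normfinder,
)

__all__ = [
    "ReferenceGeneStability",
    "ReferenceGeneStabilityResults",
    "RelativeExpression",
    "RelativeExpressionResults",
]

METHODS = ("delta_ct", "bestkeeper", "normfinder", "genorm")


class ReferenceGeneStability:
    """Candidate reference-gene stability model for one Cq table.

    Parameters
    ----------
    table
        Replicate-level Cq table; replicates enter as independent samples.
    genes
        Candidate subset to rank (default: all genes of the table).
    efficiencies
        Optional per-gene amplification factors; default E = 2 everywhere.
    """

    def __init__(
        self,
        table: CqTable,
        genes: list[str] | None = None,
        efficiencies: EfficiencyTable | None = None,
    ):
        self.table = table.subset(genes) if genes is not None else table
        if len(self.table.genes) < 3:
            raise IntegrityError("stability ranking needs at least 3 candidates")
        self.efficiencies = efficiencies

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        genes: list[str] | None = None,
        efficiencies: EfficiencyTable | None = None,
    ) -> "ReferenceGeneStability":
        """Build from a tidy frame with gene/condition/replicate/cq columns."""
        return cls(CqTable.from_long(frame), genes=genes, efficiencies=efficiencies)

    def fit(self) -> "ReferenceGeneStabilityResults":
        by_method = {
            "delta_ct": deltact_stability(self.table, self.efficiencies),
            "bestkeeper": bestkeeper(self.table),
            "normfinder": normfinder(self.table),
            "genorm": genorm(self.table, self.efficiencies),
        }
        ranking = comprehensive_ranking(
            {m: ranks_from_scores(r) for m, r in by_method.items()}
        )
        return ReferenceGeneStabilityResults(
            model=self,
            by_method=by_method,
            comprehensive=ranking,
            spread=cq_spread(self.table),
        )


@dataclass
class ReferenceGeneStabilityResults:
    """Fitted stability ranking: four method tables plus the aggregate."""

    model: ReferenceGeneStability
    by_method: dict[str, StabilityResult]
    comprehensive: ComprehensiveRanking
    spread: pd.DataFrame

    @property
    def delta_ct(self) -> StabilityResult:
        return self.by_method["delta_ct"]

    @property
    def bestkeeper(self) -> StabilityResult:
        return self.by_method["bestkeeper"]

    @property
    def normfinder(self) -> StabilityResult:
        return self.by_method["normfinder"]

    @property
    def genorm(self) -> StabilityResult:
        return self.by_method["genorm"]

    def recommended(self, n: int = 3) -> list[str]:
        """The n most stable genes of the comprehensive ranking."""
        return self.comprehensive.top(n)

    def summary(self) -> str:
        """Plain-text summary table in display order."""
        tab = self.comprehensive.table
        lines = [
            "Reference-gene stability ranking",
            "=" * 64,
            f"{'gene':<12}{'dCt':>6}{'BestK':>7}{'NormF':>7}{'geNorm':>8}"
            f"{'geomean':>9}{'final':>7}",
            "-" * 64,
        ]
        for gene, row in tab.iterrows():
            lines.append(
                f"{gene:<12}{row['delta_ct']:>6.0f}{row['bestkeeper']:>7.0f}"
                f"{row['normfinder']:>7.0f}{row['genorm']:>8.0f}"
                f"{row['geomean']:>9.3f}{int(row['final_rank']):>7}"
                + ("  (tie)" if row["tie"] else "")
            )
        lines.append("-" * 64)
        lines.append(
            "recommended references: " + ", ".join(self.recommended(3))
        )
        return "\n".join(lines)


class RelativeExpression:
    """2^-ddCt relative-quantification model for target genes."""

    def __init__(
        self,
        table: CqTable,
        targets: list[str],
        references: list[str],
        calibrator: str,
        alpha: float = 0.05,
        efficiencies: EfficiencyTable | None = None,
        efficiency_corrected: bool = False,
    ):
        self.table = table
        self.targets = list(targets)
        self.references = list(references)
        self.calibrator = calibrator
        self.alpha = alpha
        self.efficiencies = efficiencies
        self.efficiency_corrected = efficiency_corrected

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, targets, references, calibrator, **kwargs
    ) -> "RelativeExpression":
        return cls(CqTable.from_long(frame), targets, references, calibrator, **kwargs)

    def fit(self, letters: bool = True) -> "RelativeExpressionResults":
        result = delta_delta_ct(
            self.table,
            self.targets,
            self.references,
            self.calibrator,
            efficiencies=self.efficiencies,
            efficiency_corrected=self.efficiency_corrected,
        )
        result.alpha = self.alpha
        if letters:
            result = tukey_letters(result, alpha=self.alpha)
        return RelativeExpressionResults(model=self, expression=result)


@dataclass
class RelativeExpressionResults:
    model: RelativeExpression
    expression: ExpressionResult

    @property
    def summary_table(self) -> pd.DataFrame:
        return self.expression.summary

    def fold_change(self, gene: str, condition: str) -> float:
        return self.expression.fold_change(gene, condition)

    def summary(self) -> str:
        exp = self.expression
        lines = [
            "Relative expression (2^-ddCt)",
            f"references: {', '.join(exp.references)}   "
            f"calibrator: {exp.calibrator}   alpha: {exp.alpha}",
            "=" * 64,
            f"{'gene':<10}{'condition':<16}{'FC':>9}{'SEM':>9}  letters",
            "-" * 64,
        ]
        for (gene, cond), row in exp.summary.iterrows():
            lines.append(
                f"{gene:<10}{cond:<16}{row['fold_change']:>9.3f}"
                f"{row['sem']:>9.3f}  {row['letters']}"
            )
        return "\n".join(lines)
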