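"""Core domain types for reference-gene stability analysis.

Two tabular containers carry all experimental data:

* :class:`CqTable` — replicate-level qRT-PCR quantification cycles (Cq),
  one value per (gene, sample), each sample labelled with a condition and a
  replicate index.  Lower Cq means more template; one cycle is a two-fold
  difference at perfect amplification efficiency.
* :class:`CountMatrix` — RNA-Seq read counts, genes in rows, samples in
  columns, with the same condition/replicate metadata.

Both wrap pandas DataFrames and validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RefstabError",
    "FormatError",
    "ParseError",
    "IntegrityError",
    "CqTable",
    "CountMatrix",
    "EfficiencyTable",
    "RunConfig",
]


class RefstabError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RefstabError):
    """A file or table does not have the expected shape or columns."""


class ParseError(RefstabError):
    """A cell could not be interpreted (non-numeric Cq, fractional count...)."""


class IntegrityError(RefstabError):
    """The data violate a structural invariant (duplicates, zero library...)."""


META_COLUMNS = ("condition", "replicate")


def _validate_meta(meta: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    meta = meta.copy()
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise FormatError(f"sample metadata is missing column {col!r}")
    missing = [s for s in samples if s not in meta.index]
    if missing:
        raise IntegrityError(f"samples without metadata: {missing}")
    meta = meta.loc[list(samples), list(META_COLUMNS)]
    reps = pd.to_numeric(meta["replicate"], errors="coerce")
    if reps.isna().any() or (reps < 1).any() or (reps != reps.round()).any():
        raise IntegrityError("replicate indices must be integers >= 1")
    meta["replicate"] = reps.astype(int)
    meta["condition"] = meta["condition"].astype(str)
    dup = meta.duplicated(subset=["condition", "replicate"])
    if dup.any():
        pairs = meta.loc[dup, ["condition", "replicate"]].itertuples(index=False)
        raise IntegrityError(
            "duplicate (condition, replicate) pairs: "
            + ", ".join(f"({c}, {r})" for c, r in pairs)
        )
    return meta


@dataclass(frozen=True)
class CqTable:
    """Replicate-level Cq measurements, genes x samples.

    Parameters
    ----------
    values
        DataFrame indexed by gene, columns are sample identifiers, cells are
        Cq values in PCR cycles.  NaN marks a missing measurement.
    meta
        DataFrame indexed by sample with columns ``condition`` and
        ``replicate`` (integer >= 1).  Every sample column of ``values``
        must appear in ``meta``; each (condition, replicate) pair is unique.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.values.astype(float)
        if values.index.has_duplicates:
            raise IntegrityError("duplicate gene identifiers")
        if values.columns.has_duplicates:
            raise IntegrityError("duplicate sample identifiers")
        finite = np.isfinite(values.to_numpy()) | np.isnan(values.to_numpy())
        if not finite.all():
            raise ParseError("Cq values must be finite where present")
        meta = _validate_meta(self.meta, list(values.columns))
        values = values.rename_axis(index="gene", columns=None)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "meta", meta.rename_axis(index="sample"))

    # -- accessors ---------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.meta["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def condition_of(self, sample: str) -> str:
        return str(self.meta.loc[sample, "condition"])

    def replicate_of(self, sample: str) -> int:
        return int(self.meta.loc[sample, "replicate"])

    def cq(self, gene: str, sample: str) -> float:
        return float(self.values.loc[gene, sample])

    @property
    def n_cells(self) -> int:
        return int(self.values.size)

    def samples_in(self, condition: str) -> list[str]:
        return list(self.meta.index[self.meta["condition"] == condition])

    # -- manipulation ------------------------------------------------------
    def subset(self, genes: Iterable[str]) -> "CqTable":
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise IntegrityError(f"genes absent from table: {missing}")
        return CqTable(self.values.loc[genes], self.meta)

    def with_values(self, values: pd.DataFrame) -> "CqTable":
        return CqTable(values, self.meta)

    def to_long(self) -> pd.DataFrame:
        """Tidy frame with columns gene, sample, condition, replicate, cq."""
        long = (
            self.values.rename_axis(index="gene", columns="sample")
            .stack(future_stack=True)
            .rename("cq")
            .reset_index()
        )
        long["condition"] = long["sample"].map(self.meta["condition"])
        long["replicate"] = long["sample"].map(self.meta["replicate"])
        return long[["gene", "sample", "condition", "replicate", "cq"]]

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "CqTable":
        """Build from a tidy frame (gene, sample?, condition, replicate, cq).

        When no ``sample`` column is given the identifier is synthesised as
        ``condition_replicate``, which is how qPCR runs are usually labelled
        when plates only track treatment and replicate.
        """
        frame = frame.copy()
        cols = {c.lower(): c for c in frame.columns}
        for required in ("gene", "condition", "replicate", "cq"):
            if required not in cols:
                raise FormatError(f"missing column {required!r}")
        frame.columns = [c.lower() for c in frame.columns]
        if "sample" not in frame.columns:
            frame["sample"] = (
                frame["condition"].astype(str)
                + "_"
                + frame["replicate"].astype(int).astype(str)
            )
        dup = frame.duplicated(subset=["gene", "sample"])
        if dup.any():
            first = frame.loc[dup, ["gene", "sample"]].iloc[0]
            raise IntegrityError(
                f"duplicate measurement for gene {first['gene']!r}, "
                f"sample {first['sample']!r}"
            )
        # preserve first-appearance order of genes and samples
        gene_order = list(dict.fromkeys(frame["gene"]))
        sample_order = list(dict.fromkeys(frame["sample"]))
        values = frame.pivot(index="gene", columns="sample", values="cq")
        values = values.reindex(index=gene_order, columns=sample_order)
        meta = (
            frame.drop_duplicates("sample")
            .set_index("sample")[["condition", "replicate"]]
            .reindex(sample_order)
        )
        return cls(values, meta)


@dataclass(frozen=True)
class CountMatrix:
    """RNA-Seq read counts, genes x samples, with condition metadata."""

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("counts must be numeric")
        if np.isnan(arr.astype(float)).any():
            raise ParseError("counts may not be missing")
        if (arr < 0).any():
            raise ParseError("counts must be non-negative")
        if not np.array_equal(arr, np.round(arr)):
            raise ParseError("counts must be integral")
        counts = counts.astype(np.int64)
        if counts.index.has_duplicates:
            raise IntegrityError("duplicate gene identifiers")
        meta = _validate_meta(self.meta, list(counts.columns))
        if meta["condition"].nunique() < 2:
            raise IntegrityError("a count matrix needs at least 2 conditions")
        libsizes = counts.sum(axis=0)
        empty = list(libsizes.index[libsizes == 0])
        if empty:
            raise IntegrityError(f"samples with zero library size: {empty}")
        counts = counts.rename_axis(index="gene", columns=None)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "meta", meta.rename_axis(index="sample"))

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.meta["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def condition_of(self, sample: str) -> str:
        return str(self.meta.loc[sample, "condition"])

    def replicate_of(self, sample: str) -> int:
        return int(self.meta.loc[sample, "replicate"])

    def count(self, gene: str, sample: str) -> int:
        return int(self.counts.loc[gene, sample])

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_in(self, condition: str) -> list[str]:
        return list(self.meta.index[self.meta["condition"] == condition])


class EfficiencyTable:
    """Per-gene qPCR amplification efficiency.

    ``E`` is the per-cycle amplification factor: E = 2 is perfect doubling
    (often reported as 100%).  Genes not listed default to E = 2, the
    assumption under which Cq differences are directly log2 expression
    differences.
    """

    def __init__(self, efficiencies: Mapping[str, float] | None = None):
        self._e: dict[str, float] = {}
        if efficiencies:
            for gene, e in efficiencies.items():
                e = float(e)
                if not (1.0 < e <= 2.0):
                    raise IntegrityError(
                        f"efficiency for {gene!r} must satisfy 1 < E <= 2, got {e}"
                    )
                self._e[str(gene)] = e

    @classmethod
    def from_percent(cls, percents: Mapping[str, float]) -> "EfficiencyTable":
        """Build from the percentage convention 100*(E-1), e.g. 83 -> E=1.83."""
        return cls({g: 1.0 + float(p) / 100.0 for g, p in percents.items()})

    def efficiency(self, gene: str) -> float:
        return self._e.get(gene, 2.0)

    def weight(self, gene: str) -> float:
        """log2(E): the factor converting Cq cycles to log2 expression units."""
        return float(np.log2(self.efficiency(gene)))

    def __contains__(self, gene: str) -> bool:
        return gene in self._e


@dataclass
class RunConfig:
    """Run-level configuration shared across pipeline stages."""

    calibrator: str | None = None
    reference_genes: tuple[str, ...] = ()
    target_genes: tuple[str, ...] = ()
    screen_k: int = 4
    normalization: str = "total"  # total-count or upper-quartile
    alpha: float = 0.05
    n_recommended: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.screen_k < 1:
            raise IntegrityError("screen_k must be >= 1")
        if self.normalization not in ("total", "uq"):
            raise IntegrityError("normalization must be 'total' or 'uq'")
        if not (0 < self.alpha < 1):
            raise IntegrityError("alpha must lie in (0, 1)")
        self.reference_genes = tuple(self.reference_genes)
        self.target_genes = tuple(self.target_genes)
        overlap = set(self.reference_genes) & set(self.target_genes)
        if overlap:
            raise IntegrityError(
                f"genes cannot be both reference and target: {sorted(overlap)}"
            )

    def validate_against(self, table: CqTable) -> None:
        if self.calibrator is not None and self.calibrator not in table.conditions:
            raise IntegrityError(
                f"calibrator {self.calibrator!r} is not a condition of the table"
            )
        for g in (*self.reference_genes, *self.target_genes):
            if g not in table.values.index:
                raise IntegrityError(f"gene {g!r} absent from Cq table")
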