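"""Published per-method stability rankings for potato cyst nematodes.

These are the per-method rank orders (most stable first) reported for 11
candidate reference genes in *Globodera rostochiensis* — once from RNA-Seq
read counts and once from qRT-PCR Cq values — and for 10 candidates in the
sister species *G. pallida* (qRT-PCR).  The stepwise-exclusion (geNorm)
columns for *G. rostochiensis* end in an inseparable best pair, reported
tied at rank 1 with competition ranking afterwards.

They serve as reference inputs: feeding the per-method rank vectors into
:func:`refstab.aggregate.comprehensive_ranking` reproduces the published
comprehensive orders for both *G. rostochiensis* datasets exactly.  For the
*G. pallida* dataset, geometric-mean aggregation of the printed per-method
columns reproduces the published top (AMA-1) and bottom (Act-1) positions
but permutes the published middle order (PMP-3/mce1/aaRS); the published
middle positions there are not derivable from the printed columns by this
aggregation and are therefore not asserted anywhere in this package.
"""

from __future__ import annotations

import pandas as pd

from .aggregate import ComprehensiveRanking, comprehensive_ranking, ranks_from_order

__all__ = [
    "PublishedRanking",
    "GROSTO_RNASEQ",
    "GROSTO_QPCR",
    "GPALLIDA_QPCR",
    "published_rank_vectors",
    "aggregate_published",
]


class PublishedRanking(dict):
    """Per-method rank orders plus the published comprehensive order."""

    def __init__(
        self,
        delta_ct: list[str],
        bestkeeper: list[str],
        normfinder: list[str],
        genorm: list[str],
        genorm_tied_pair: bool,
        comprehensive: list[str],
    ):
        super().__init__(
            delta_ct=delta_ct,
            bestkeeper=bestkeeper,
            normfinder=normfinder,
            genorm=genorm,
        )
        self.genorm_tied_pair = genorm_tied_pair
        self.comprehensive = comprehensive

    @property
    def genes(self) -> list[str]:
        return list(self["delta_ct"])


# G. rostochiensis, RNA-Seq read counts
GROSTO_RNASEQ = PublishedRanking(
    delta_ct=["GR", "aaRS", "PMP-3", "ArgRS", "mce1", "MDH-1", "AMA-1",
              "CSQ-1", "Y45F10D.4", "Act-1", "EIF-3"],
    bestkeeper=["ArgRS", "PMP-3", "aaRS", "GR", "MDH-1", "mce1", "AMA-1",
                "Y45F10D.4", "CSQ-1", "Act-1", "EIF-3"],
    normfinder=["GR", "mce1", "AMA-1", "aaRS", "PMP-3", "ArgRS", "MDH-1",
                "CSQ-1", "Y45F10D.4", "Act-1", "EIF-3"],
    genorm=["ArgRS", "PMP-3", "aaRS", "GR", "MDH-1", "mce1", "AMA-1",
            "Y45F10D.4", "CSQ-1", "Act-1", "EIF-3"],
    genorm_tied_pair=True,
    comprehensive=["GR", "ArgRS", "PMP-3", "aaRS", "mce1", "AMA-1", "MDH-1",
                   "CSQ-1", "Y45F10D.4", "Act-1", "EIF-3"],
)

# G. rostochiensis, qRT-PCR Cq values
GROSTO_QPCR = PublishedRanking(
    delta_ct=["GR", "PMP-3", "AMA-1", "CSQ-1", "aaRS", "MDH-1", "mce1",
              "Y45F10D.4", "ArgRS", "EIF-3", "Act-1"],
    bestkeeper=["Y45F10D.4", "MDH-1", "GR", "Act-1", "mce1", "AMA-1",
                "PMP-3", "ArgRS", "CSQ-1", "aaRS", "EIF-3"],
    normfinder=["GR", "PMP-3", "AMA-1", "CSQ-1", "MDH-1", "aaRS",
                "Y45F10D.4", "mce1", "EIF-3", "ArgRS", "Act-1"],
    genorm=["aaRS", "PMP-3", "CSQ-1", "AMA-1", "GR", "mce1", "Y45F10D.4",
            "MDH-1", "ArgRS", "EIF-3", "Act-1"],
    genorm_tied_pair=True,
    comprehensive=["GR", "PMP-3", "AMA-1", "aaRS", "Y45F10D.4", "CSQ-1",
                   "MDH-1", "mce1", "Act-1", "ArgRS", "EIF-3"],
)

# G. pallida, qRT-PCR Cq values (10 genes; no tied pair printed)
GPALLIDA_QPCR = PublishedRanking(
    delta_ct=["AMA-1", "GR", "mce1", "aaRS", "Y45F10D.4", "PMP-3", "MDH-1",
              "EIF-3", "CSQ-1", "Act-1"],
    bestkeeper=["PMP-3", "aaRS", "GR", "Y45F10D.4", "EIF-3", "AMA-1",
                "mce1", "CSQ-1", "MDH-1", "Act-1"],
    normfinder=["GR", "AMA-1", "aaRS", "PMP-3", "mce1", "Y45F10D.4",
                "MDH-1", "EIF-3", "CSQ-1", "Act-1"],
    genorm=["AMA-1", "mce1", "GR", "Y45F10D.4", "MDH-1", "aaRS", "PMP-3",
            "EIF-3", "CSQ-1", "Act-1"],
    genorm_tied_pair=False,
    comprehensive=["AMA-1", "GR", "PMP-3", "mce1", "aaRS", "Y45F10D.4",
                   "MDH-1", "EIF-3", "CSQ-1", "Act-1"],
)


def published_rank_vectors(dataset: PublishedRanking) -> dict[str, pd.Series]:
    """Per-method rank vectors (gene -> rank) for one published dataset."""
    vectors = {}
    for method in ("delta_ct", "bestkeeper", "normfinder", "genorm"):
        tied = dataset.genorm_tied_pair and method == "genorm"
        vectors[method] = ranks_from_order(dataset[method], tied_first_pair=tied)
    genes = dataset.genes
    return {m: v.reindex(genes) for m, v in vectors.items()}


def aggregate_published(dataset: PublishedRanking) -> ComprehensiveRanking:
    """Geometric-mean aggregation of one published dataset's rank columns."""
    return comprehensive_ranking(published_rank_vectors(dataset))
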