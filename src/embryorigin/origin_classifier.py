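"""Parental-origin classification of embryo-expressed RNAs.

Pre-EGA (2-4 cell) embryos transcribe little of their own genome, so the
RNAs they contain are mostly inherited.  Each gene expressed in the embryo
is assigned one of four confident origin labels by presence/absence in the
gamete datasets — detected in both sperm and oocyte, oocyte only, sperm
only, or in neither gamete (embryo-exclusive, candidate minor-EGA
transcripts) — or *provisional* when the two oocyte references disagree.
Provisional genes appear in the assignment table but are excluded from the
four confident counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .expression_calls import (
    Consensus,
    Status,
    ThresholdConfig,
    call_count_table,
    call_intensity_table,
    oocyte_consensus,
    status_of,
)


class OriginLabel(str, enum.Enum):
    SPERM_AND_OOCYTE = "sperm_and_oocyte"
    OOCYTE_ONLY = "oocyte_only"
    SPERM_ONLY = "sperm_only"
    EMBRYO_ONLY = "embryo_only"
    PROVISIONAL = "provisional"


CONFIDENT_LABELS = (
    OriginLabel.SPERM_AND_OOCYTE,
    OriginLabel.OOCYTE_ONLY,
    OriginLabel.SPERM_ONLY,
    OriginLabel.EMBRYO_ONLY,
)

#: Column order of the assignment table written by :func:`classify_all`.
ASSIGNMENT_COLUMNS = (
    "gene_id",
    "label",
    "embryo",
    "sperm",
    "oocyte_ref1",
    "oocyte_ref2",
    "oocyte_consensus",
)


@dataclass(frozen=True)
class OriginSummary:
    """Counts per confident origin label plus the provisional count.

    Invariants (checked at construction): the four confident counts sum to
    ``total_confident``, and confident plus provisional genes account for
    every embryo-expressed gene.
    """

    counts: dict[OriginLabel, int]
    provisional: int
    total_confident: int
    total_embryo_expressed: int

    def __post_init__(self) -> None:
        s = sum(self.counts[lbl] for lbl in CONFIDENT_LABELS)
        if s != self.total_confident:
            raise ValueError(
                f"confident counts sum to {s}, not {self.total_confident}"
            )
        if self.total_confident + self.provisional != self.total_embryo_expressed:
            raise ValueError(
                "confident + provisional != embryo-expressed total: "
                f"{self.total_confident} + {self.provisional} != "
                f"{self.total_embryo_expressed}"
            )

    @classmethod
    def from_counts(
        cls,
        sperm_and_oocyte: int,
        oocyte_only: int,
        sperm_only: int,
        embryo_only: int,
        provisional: int = 0,
    ) -> "OriginSummary":
        """Build (and validate) a summary from per-category counts, e.g.
        published totals."""
        counts = {
            OriginLabel.SPERM_AND_OOCYTE: sperm_and_oocyte,
            OriginLabel.OOCYTE_ONLY: oocyte_only,
            OriginLabel.SPERM_ONLY: sperm_only,
            OriginLabel.EMBRYO_ONLY: embryo_only,
        }
        total = sperm_and_oocyte + oocyte_only + sperm_only + embryo_only
        return cls(counts, provisional, total, total + provisional)

    def as_dict(self) -> dict[str, int]:
        d = {lbl.value: self.counts[lbl] for lbl in CONFIDENT_LABELS}
        d["provisional"] = self.provisional
        d["total_confident"] = self.total_confident
        d["total_embryo_expressed"] = self.total_embryo_expressed
        return d


def classify_gene(
    embryo: Status, sperm: Status, oocyte: Consensus
) -> OriginLabel:
    """Origin label for one embryo-expressed gene.

    The sperm side has a single dataset, so not_measured there counts as
    not-found; the oocyte side arrives as the two-reference consensus, and
    an ambiguous consensus forces the provisional label regardless of the
    sperm call.
    """
    if embryo != Status.EXPRESSED:
        raise ValueError(
            "classify_gene requires an embryo-expressed gene; "
            "non-expressed genes are omitted from the analysis"
        )
    if oocyte == Consensus.AMBIGUOUS:
        return OriginLabel.PROVISIONAL
    in_sperm = sperm == Status.EXPRESSED
    in_oocyte = oocyte == Consensus.EXPRESSED
    if in_sperm and in_oocyte:
        return OriginLabel.SPERM_AND_OOCYTE
    if in_sperm:
        return OriginLabel.SPERM_ONLY
    if in_oocyte:
        return OriginLabel.OOCYTE_ONLY
    return OriginLabel.EMBRYO_ONLY


def classify_all(
    embryo_calls: Mapping[str, Status],
    sperm_calls: Mapping[str, Status],
    oocyte_calls_pair: tuple[Mapping[str, Status], Mapping[str, Status]],
) -> tuple[pd.DataFrame, OriginSummary]:
    """Classify every embryo-expressed gene; genes not expressed in any
    embryo sample are omitted.

    Call sets must share a harmonized gene-identifier namespace (exact
    string match, probe-to-gene mapping already applied).  Returns the
    assignment table (ASSIGNMENT_COLUMNS order) and its summary; the five
    labels partition the embryo-expressed set by construction, and the
    summary invariants are re-checked against the raw rows.
    """
    ref1, ref2 = oocyte_calls_pair
    genes = sorted(
        g for g, st in embryo_calls.items() if st == Status.EXPRESSED
    )
    if not genes:
        import logging

        logging.getLogger(__name__).warning("no embryo-expressed genes")

    rows = []
    tally = {lbl: 0 for lbl in OriginLabel}
    for gene in genes:
        s_sperm = status_of(sperm_calls, gene)
        s1 = status_of(ref1, gene)
        s2 = status_of(ref2, gene)
        cons = oocyte_consensus(s1, s2)
        label = classify_gene(Status.EXPRESSED, s_sperm, cons)
        tally[label] += 1
        rows.append(
            (gene, label.value, Status.EXPRESSED.value, s_sperm.value,
             s1.value, s2.value, cons.value)
        )
    table = pd.DataFrame(rows, columns=list(ASSIGNMENT_COLUMNS))
    confident = {lbl: tally[lbl] for lbl in CONFIDENT_LABELS}
    summary = OriginSummary(
        counts=confident,
        provisional=tally[OriginLabel.PROVISIONAL],
        total_confident=sum(confident.values()),
        total_embryo_expressed=len(genes),
    )
    assert summary.total_embryo_expressed == len(table)
    return table, summary


def classify_dataset(
    embryo,
    sperm,
    oocyte_array,
    oocyte_rnaseq,
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> tuple[pd.DataFrame, OriginSummary]:
    """End-to-end classification from raw tables.

    ``embryo``, ``sperm`` and ``oocyte_rnaseq`` are GeneCountTables;
    ``oocyte_array`` is an IntensityTable (the first oocyte reference).
    Presence calls are made with the configured thresholds and fed to
    :func:`classify_all`.
    """
    return classify_all(
        call_count_table(embryo, thresholds),
        call_count_table(sperm, thresholds),
        (
            call_intensity_table(oocyte_array, thresholds),
            call_count_table(oocyte_rnaseq, thresholds),
        ),
    )


def annotate_de_origins(
    de: pd.DataFrame, assignments: pd.DataFrame
) -> dict[str, int]:
    """Break down the significant DE genes by origin label.

    ``de`` needs gene_id and significant columns; every significant gene
    must be present in the assignment table.  Returns per-label counts
    (confident labels and provisional) summing to the number of
    significant genes.
    """
    label_by_gene = dict(zip(assignments["gene_id"], assignments["label"]))
    counts = {lbl.value: 0 for lbl in OriginLabel}
    for gene in de.loc[de["significant"], "gene_id"]:
        if gene not in label_by_gene:
            raise KeyError(
                f"differentially expressed gene {gene!r} has no origin "
                "assignment"
            )
        counts[label_by_gene[gene]] += 1
    return counts


def venn_figure(summary: OriginSummary, path: str) -> None:
    """Two-circle Venn of sperm- and oocyte-detected genes within the
    embryo-expressed universe (embryo-only genes sit outside both circles).

    A reporting convenience derived from the summary, never a source of
    truth.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    c = summary.counts
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.add_patch(Circle((-0.55, 0), 1.0, alpha=0.4, color="tab:blue"))
    ax.add_patch(Circle((0.55, 0), 1.0, alpha=0.4, color="tab:orange"))
    ax.text(-1.1, 0, str(c[OriginLabel.SPERM_ONLY]), ha="center", fontsize=14)
    ax.text(0, 0, str(c[OriginLabel.SPERM_AND_OOCYTE]), ha="center", fontsize=14)
    ax.text(1.1, 0, str(c[OriginLabel.OOCYTE_ONLY]), ha="center", fontsize=14)
    ax.text(-1.1, 1.15, "sperm", ha="center")
    ax.text(1.1, 1.15, "oocyte", ha="center")
    ax.text(0, -1.45,
            f"embryo only: {c[OriginLabel.EMBRYO_ONLY]}   "
            f"provisional: {summary.provisional}", ha="center")
    ax.set_xlim(-2, 2)
    ax.set_ylim(-1.8, 1.6)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(
        f"Parental origin of {summary.total_embryo_expressed} "
        "embryo-expressed RNAs"
    )
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
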