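"""Tri-state presence calls and the oocyte two-reference consensus.

A gene is called *expressed* in an RNA-seq dataset when its raw read count
is strictly greater than ``min_reads`` (default 5) in at least
``min_samples`` samples (default 1); on the microarray reference a gene is
expressed when any of its probes reaches ``array_min_intensity`` raw units
(default 40, inclusive — it is a *minimum* threshold).  A gene absent from
a platform's measured universe is *not_measured*.

The oocyte consensus reconciles the two oocyte references (one microarray,
one RNA-seq): agreement yields a confident call, while a gene detected in
only one reference is *ambiguous* and will be labeled provisional
downstream.  ``not_measured`` counts as not-found for consensus purposes,
so detection in one reference with no measurement in the other is still
ambiguous: absence of evidence on one platform must not create a confident
call.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io_formats import GeneCountTable, IntensityTable


class Status(str, enum.Enum):
    EXPRESSED = "expressed"
    NOT_EXPRESSED = "not_expressed"
    NOT_MEASURED = "not_measured"


class Consensus(str, enum.Enum):
    EXPRESSED = "expressed"
    NOT_EXPRESSED = "not_expressed"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ThresholdConfig:
    """All fixed thresholds of the pipeline, in one place.

    min_reads : int
        Read-count cutoff, strict ("greater than five reads"); a count of
        exactly 5 does not qualify.
    min_samples : int
        Number of samples that must pass min_reads ("in at least one").
    array_min_intensity : float
        Raw-intensity cutoff, inclusive (a *minimum* threshold of 40).
    ct_max : float
        qPCR quantification limit; CT strictly above this is beyond
        quantification.
    fold_validation : float
        Per-replicate qPCR concordance threshold (1.5-fold), inclusive by
        default (`fold_boundary_inclusive`).
    fdr_cutoff : float
        BH-FDR significance cutoff, strict (q < 0.10).
    """

    min_reads: int = 5
    min_samples: int = 1
    array_min_intensity: float = 40.0
    ct_max: float = 33.0
    fold_validation: float = 1.5
    fdr_cutoff: float = 0.10
    fold_boundary_inclusive: bool = True

    def __post_init__(self) -> None:
        for name in ("min_reads", "min_samples", "array_min_intensity",
                     "ct_max", "fold_validation", "fdr_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be > 0")


def call_expressed_counts(counts, thresholds: ThresholdConfig = ThresholdConfig()) -> Status:
    """Presence call from a vector of raw read counts (one per sample)."""
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("empty count vector")
    if (arr < 0).any():
        raise ValueError("negative read count")
    n_pass = int((arr > thresholds.min_reads).sum())
    return Status.EXPRESSED if n_pass >= thresholds.min_samples else Status.NOT_EXPRESSED


def call_expressed_microarray(
    intensities, thresholds: ThresholdConfig = ThresholdConfig()
) -> Status:
    """Presence call from per-probe (replicate-averaged) raw intensities.

    An empty vector means the gene is absent from the array design and is
    therefore not_measured.  Probes are redundant detectors of the same
    transcript, so any probe at or above the cutoff suffices.
    """
    arr = np.asarray(intensities, dtype=float)
    if arr.size == 0:
        return Status.NOT_MEASURED
    if (arr < 0).any():
        raise ValueError("negative intensity")
    if (arr >= thresholds.array_min_intensity).any():
        return Status.EXPRESSED
    return Status.NOT_EXPRESSED


def oocyte_consensus(call_a: Status, call_b: Status) -> Consensus:
    """Consensus of the two oocyte reference calls.

    Found in both -> expressed; found in neither (not_expressed or
    not_measured) -> not_expressed; found in exactly one -> ambiguous
    (downstream: provisional).
    """
    a_found = call_a == Status.EXPRESSED
    b_found = call_b == Status.EXPRESSED
    if a_found and b_found:
        return Consensus.EXPRESSED
    if not a_found and not b_found:
        return Consensus.NOT_EXPRESSED
    return Consensus.AMBIGUOUS


def call_count_table(
    table: GeneCountTable, thresholds: ThresholdConfig = ThresholdConfig()
) -> dict[str, Status]:
    """Vectorized presence call for every gene of a count table."""
    arr = table.counts.to_numpy()
    n_pass = (arr > thresholds.min_reads).sum(axis=1)
    expressed = n_pass >= thresholds.min_samples
    return {
        gene: (Status.EXPRESSED if ok else Status.NOT_EXPRESSED)
        for gene, ok in zip(table.counts.index, expressed)
    }


def call_intensity_table(
    table: IntensityTable, thresholds: ThresholdConfig = ThresholdConfig()
) -> dict[str, Status]:
    """Presence call per gene from a probe intensity table.

    Probes are first averaged over array replicates, then grouped by gene;
    genes with no mapped probe do not appear (they are not_measured on
    this platform).
    """
    return {
        gene: call_expressed_microarray(vals, thresholds)
        for gene, vals in table.gene_intensities().items()
    }


def status_of(calls: Mapping[str, Status], gene: str) -> Status:
    """Status of a gene in a call set; absent from the measured universe
    means not_measured."""
    return calls.get(gene, Status.NOT_MEASURED)
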