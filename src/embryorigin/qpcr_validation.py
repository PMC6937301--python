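"""qRT-PCR validation: reference-gene choice, 2^-ddCT folds, concordance.

Relative expression follows the 2^-ddCT convention: dCT = CT_target -
CT_reference within a condition, ddCT = dCT_case - dCT_control, and the
fold change is 2^-ddCT.  Any input CT above the quantification limit
(default 33 cycles, strict) or missing makes the replicate unquantifiable
— a value, not an error, because assays near the detection limit are an
expected outcome.

A replicate *validates* the sequencing result when its fold agrees in
direction and magnitude with the RNA-seq call: fold >= 1.5 for an
up-regulated gene, fold <= 1/1.5 for a down-regulated one (boundary
inclusive by default).  Across replicates, significance is a two-sided
paired t-test on the normalized expression values (dCT), not on folds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression_calls import ThresholdConfig
from .io_formats import QpcrTable

logger = logging.getLogger(__name__)

#: Column order of the validation summary table (one row per gene,
#: mirroring a published-style results table).
VALIDATION_COLUMNS = (
    "gene_id", "mean_fold", "sd_fold", "n_validated", "paired_t_p",
    "n_quantifiable", "rnaseq_direction",
)


@dataclass(frozen=True)
class FoldChangeRecord:
    """One replicate's 2^-ddCT fold change; unquantifiable when any of
    the four CTs is missing or beyond the CT limit."""

    gene_id: str
    replicate: int
    fold: float  # NaN when not quantifiable
    delta_ct_case: float
    delta_ct_control: float

    @property
    def quantifiable(self) -> bool:
        return not math.isnan(self.fold)


@dataclass
class ValidationSummary:
    """Per-gene summary across replicates: folds, validated count, paired-t."""

    gene_id: str
    rnaseq_direction: str  # "up" | "down"
    folds: list[float] = field(default_factory=list)  # quantifiable only
    n_validated: int = 0
    mean_fold: float = float("nan")
    sd_fold: float = float("nan")
    paired_t_p: float = float("nan")

    @property
    def quantifiable(self) -> bool:
        return len(self.folds) > 0


def _quantifiable_ct(ct: float, thresholds: ThresholdConfig) -> bool:
    return not math.isnan(ct) and ct <= thresholds.ct_max


def select_reference_gene(
    qpcr: QpcrTable,
    candidates: list[str],
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> str:
    """Pick the most stable candidate reference gene.

    Stability is measured as the standard deviation of the candidate's
    quantifiable CT values across all samples (smaller = more stable);
    ties break lexicographically.  Candidates with fewer than two
    quantifiable CTs are excluded with a warning.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate reference genes")
    sds: dict[str, float] = {}
    for gene in candidates:
        cts = qpcr.records.loc[
            qpcr.records["gene_id"] == gene, "ct"
        ].to_numpy(dtype=float)
        cts = cts[~np.isnan(cts)]
        cts = cts[cts <= thresholds.ct_max]
        if cts.size < 2:
            logger.warning(
                "reference candidate %s excluded: fewer than 2 "
                "quantifiable CTs", gene,
            )
            continue
        sds[gene] = float(np.std(cts, ddof=1))
    if not sds:
        raise ValueError("no candidate reference gene has >= 2 quantifiable CTs")
    return min(sds, key=lambda g: (sds[g], g))


def fold_change_ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_control: float,
    ct_ref_control: float,
    thresholds: ThresholdConfig = ThresholdConfig(),
    gene_id: str = "",
    replicate: int = 0,
) -> FoldChangeRecord:
    """2^-ddCT fold change for one replicate.

    dCT = CT_target - CT_ref per condition; ddCT = dCT_case - dCT_control;
    fold = 2^-ddCT.  Any CT missing or above the quantification limit
    yields an unquantifiable record (fold = NaN).
    """
    cts = (ct_target_case, ct_ref_case, ct_target_control, ct_ref_control)
    if any(not _quantifiable_ct(c, thresholds) for c in cts):
        return FoldChangeRecord(gene_id, replicate, float("nan"),
                                float("nan"), float("nan"))
    d_case = ct_target_case - ct_ref_case
    d_control = ct_target_control - ct_ref_control
    fold = 2.0 ** (-(d_case - d_control))
    return FoldChangeRecord(gene_id, replicate, fold, d_case, d_control)


def replicate_validates(
    fold: float, direction: str, thresholds: ThresholdConfig
) -> bool:
    """Direction-aware concordance with sequencing at the fold threshold."""
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    thr = thresholds.fold_validation
    if direction == "up":
        return fold >= thr if thresholds.fold_boundary_inclusive else fold > thr
    inv = 1.0 / thr
    return fold <= inv if thresholds.fold_boundary_inclusive else fold < inv


def paired_t_test(x, y) -> tuple[float, float]:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)) on d = x - y,
    df = n - 1.

    Degenerate cases: zero difference variance with zero mean difference
    gives (0, 1); zero variance with nonzero mean difference gives an
    infinite t (p -> 0) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired t-test needs equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        logger.warning("zero variance of differences with nonzero mean: "
                       "t is infinite, p -> 0")
        return math.copysign(math.inf, mean), 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return t, p


def summarize_validation(
    folds: list[FoldChangeRecord],
    rnaseq_direction: str,
    thresholds: ThresholdConfig = ThresholdConfig(),
    fold_average: str = "arithmetic",
) -> ValidationSummary:
    """Summarize one gene's replicates: validated count, mean/SD of folds,
    paired t-test on the (dCT_case, dCT_control) pairs.

    Zero quantifiable replicates returns an unquantifiable summary (all
    statistics NaN) rather than raising — the published analogue is a row
    reported as beyond the CT limit.
    """
    if not folds:
        raise ValueError("need at least one fold-change record")
    gene = folds[0].gene_id
    quant = [f for f in folds if f.quantifiable]
    summary = ValidationSummary(gene_id=gene, rnaseq_direction=rnaseq_direction)
    if not quant:
        return summary
    vals = np.array([f.fold for f in quant])
    summary.folds = [float(v) for v in vals]
    summary.n_validated = sum(
        replicate_validates(f, rnaseq_direction, thresholds) for f in vals
    )
    if fold_average == "arithmetic":
        summary.mean_fold = float(vals.mean())
    elif fold_average == "geometric":
        summary.mean_fold = float(np.exp(np.log(vals).mean()))
    else:
        raise ValueError(f"unknown fold_average {fold_average!r}")
    summary.sd_fold = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    if len(quant) >= 2:
        _, summary.paired_t_p = paired_t_test(
            [f.delta_ct_case for f in quant],
            [f.delta_ct_control for f in quant],
        )
    return summary


def validate_genes(
    qpcr: QpcrTable,
    directions: dict[str, str],
    reference_gene: str,
    thresholds: ThresholdConfig = ThresholdConfig(),
    case_group: str = "high",
    control_group: str = "low",
) -> pd.DataFrame:
    """Run the full validation for every gene in ``directions``.

    ``directions`` maps gene_id -> "up"/"down" (the RNA-seq call, case
    over control).  Returns one row per gene in VALIDATION_COLUMNS order.
    """
    replicates = sorted(qpcr.records["replicate"].unique())
    rows = []
    for gene, direction in directions.items():
        recs = []
        for rep in replicates:
            recs.append(
                fold_change_ddct(
                    qpcr.ct(rep, case_group, gene),
                    qpcr.ct(rep, case_group, reference_gene),
                    qpcr.ct(rep, control_group, gene),
                    qpcr.ct(rep, control_group, reference_gene),
                    thresholds, gene_id=gene, replicate=rep,
                )
            )
        s = summarize_validation(recs, direction, thresholds)
        rows.append(
            (gene, s.mean_fold, s.sd_fold, s.n_validated, s.paired_t_p,
             len(s.folds), direction)
        )
    return pd.DataFrame(rows, columns=list(VALIDATION_COLUMNS))
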