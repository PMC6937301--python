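"""Negative-binomial exact-test differential expression with BH-FDR.

Two-group comparison of embryo count profiles (high- vs low-fertility
sires) under the negative-binomial model with a single common dispersion
shared across genes: a gene's count has mean :math:`m` and variance
:math:`m + \\phi m^2`, so :math:`\\phi = 0` reduces to Poisson.

The pipeline is: equalize library sizes by scaling each sample to the
geometric-mean depth (counts scaled then rounded, so samples become
exchangeable), estimate the common dispersion by Cox-Reid adjusted profile
likelihood, then for each gene compute a conditional exact test: given the
gene's total count across both groups, the group-A sum follows the
convolution-conditional distribution of two NB sums, and the two-sided
p-value is the total probability of all splits no more likely than the
observed one.  P-values are corrected by the Benjamini-Hochberg step-up
and genes are flagged significant at q < the FDR cutoff (default 0.10,
strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .expression_calls import Status, ThresholdConfig, call_count_table
from .io_formats import GeneCountTable

#: Relative tolerance when deciding whether a split's probability ties the
#: observed one in the two-sided "sum of outcomes no more likely" rule.
_TIE_RTOL = 1e-12

#: Dispersions at or below this are treated as Poisson.
_POISSON_EPS = 1e-12

#: Pseudo-count added to each normalized group mean in the log2 fold change.
LOG2FC_PSEUDOCOUNT = 0.5

#: Column order of the DE result table.
DE_COLUMNS = (
    "gene_id", "log2fc", "pvalue", "qvalue", "significant",
    "mean_norm_count", "tested",
)


@dataclass(frozen=True)
class DispersionEstimate:
    """Common NB dispersion shared across genes; zero means Poisson."""

    common_dispersion: float
    method: str = "cox-reid-apl"

    def __post_init__(self) -> None:
        if self.common_dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def equalize_library_sizes(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale every sample to the geometric-mean library size and round.

    The exact test conditions on a gene's total count, which requires the
    samples to be exchangeable under the null; equalizing depths is the
    simplest documented way to get there.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("sample with zero library size")
    target = np.exp(np.log(lib).mean())
    scaled = counts.to_numpy(dtype=float) * (target / lib)[None, :]
    return pd.DataFrame(
        np.rint(scaled).astype(np.int64), index=counts.index,
        columns=counts.columns,
    )


def _nb_loglik(counts: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB log-likelihood with per-row means ``mu`` shared across columns.

    Rows with zero mean contribute 0 (their counts are necessarily 0).
    """
    pos = mu > 0
    if not pos.any():
        return 0.0
    y = counts[pos]
    m = mu[pos][:, None]
    if phi <= _POISSON_EPS:
        return float(stats.poisson.logpmf(y, m).sum())
    r = 1.0 / phi
    p = r / (r + m)
    return float(stats.nbinom.logpmf(y, r, p).sum())


def _cox_reid_adjustment(mu: np.ndarray, n_samples: int, phi: float) -> float:
    """0.5 * log of the observed information about each group mean,
    summed over gene-groups; removes the downward bias of plain profile
    likelihood at small sample counts."""
    pos = mu > 0
    if not pos.any():
        return 0.0
    info = n_samples * mu[pos] / (1.0 + phi * mu[pos])
    return 0.5 * float(np.log(info).sum())


def estimate_common_dispersion(
    table: GeneCountTable,
    groups: Mapping[str, str] | None = None,
) -> DispersionEstimate:
    """Maximize the Cox-Reid adjusted profile likelihood over a single
    dispersion, with group-wise gene means profiled out.

    ``groups`` maps sample_id -> group label; defaults to the embryo
    samples' fertility groups.  Requires at least two samples per group.
    Raises on an all-zero count matrix (no information about dispersion).
    """
    groups = groups or fertility_groups(table)
    if int(table.counts.to_numpy().sum()) == 0:
        raise ValueError("all-zero count matrix: dispersion is undefined")
    counts = equalize_library_sizes(table.counts)
    labels = sorted(set(groups.values()))
    blocks = []
    for lab in labels:
        ids = [s for s in counts.columns if groups.get(s) == lab]
        if len(ids) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
        blocks.append(counts[ids].to_numpy())
    if all(b.sum() == 0 for b in blocks):
        raise ValueError("all-zero count matrix: dispersion is undefined")

    mus = [b.mean(axis=1) for b in blocks]

    def neg_apl(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        ll = 0.0
        for b, mu in zip(blocks, mus):
            ll += _nb_loglik(b, mu, phi)
            ll -= _cox_reid_adjustment(mu, b.shape[1], phi)
        return -ll

    res = optimize.minimize_scalar(
        neg_apl, bounds=(np.log(1e-8), np.log(10.0)), method="bounded",
        options={"xatol": 1e-6},
    )
    phi = float(np.exp(res.x))
    if phi <= 2e-8:  # pinned to the lower bound: effectively Poisson
        phi = 0.0
    return DispersionEstimate(phi)


def _group_sum_logpmf(
    s: np.ndarray, n_samples: int, mu: float, phi: float
) -> np.ndarray:
    """log P(sum of ``n_samples`` iid NB(mu, phi) counts = s).

    The sum of n iid NB(size r, p) variables is NB(size n*r, p); at
    phi = 0 it is Poisson(n * mu).
    """
    if phi <= _POISSON_EPS:
        return stats.poisson.logpmf(s, n_samples * mu)
    r = n_samples / phi
    p = 1.0 / (1.0 + phi * mu)
    return stats.nbinom.logpmf(s, r, p)


def nb_exact_test(
    counts_a: Sequence[int], counts_b: Sequence[int], dispersion: float
) -> float:
    """Two-sided conditional exact p-value for a two-group NB comparison.

    Assumes library sizes were equalized so the per-sample null mean is
    the pooled mean.  Conditions on the total t = sum(a) + sum(b): under
    the null the split (S_a, t - S_a) has probability proportional to
    P_a(s) * P_b(t - s), and the p-value sums the probabilities of all
    splits whose probability is <= the observed one (ties included at
    relative tolerance 1e-12).
    """
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative counts")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    s_a, t = int(a.sum()), int(a.sum() + b.sum())
    if t == 0:
        return 1.0
    mu = t / (len(a) + len(b))
    s = np.arange(t + 1)
    logp = (
        _group_sum_logpmf(s, len(a), mu, dispersion)
        + _group_sum_logpmf(t - s, len(b), mu, dispersion)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    keep = p <= p[s_a] * (1.0 + _TIE_RTOL)
    return float(min(1.0, p[keep].sum()))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, restored to input order.

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) over the ascending sort.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def fertility_groups(table: GeneCountTable) -> dict[str, str]:
    """sample_id -> fertility group for the embryo samples of a table."""
    out = {
        s.sample_id: s.fertility_group
        for s in table.samples
        if s.tissue == "embryo" and s.fertility_group in ("high", "low")
    }
    if not out:
        raise ValueError("no embryo samples with high/low fertility labels")
    return out


def run_de(
    table: GeneCountTable,
    groups: Mapping[str, str] | None = None,
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> pd.DataFrame:
    """Full DE pipeline on an embryo count table.

    Genes failing the embryo presence call (the expressed-gene universe)
    are excluded from testing and flagged ``tested = False`` with NaN
    statistics.  log2fc is high over low on normalized group means with a
    0.5 pseudo-count.  Returns a DataFrame in DE_COLUMNS order.
    """
    groups = groups or fertility_groups(table)
    sub = table.subset_samples(list(groups))
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    # "high" (or the lexicographically later label) is the numerator
    lab_lo, lab_hi = (
        ("low", "high") if set(labels) == {"high", "low"} else tuple(labels)
    )

    expressed = call_count_table(sub, thresholds)
    tested_mask = np.array(
        [expressed[g] == Status.EXPRESSED for g in sub.counts.index]
    )

    norm = equalize_library_sizes(sub.counts)
    cols_hi = [s for s in norm.columns if groups[s] == lab_hi]
    cols_lo = [s for s in norm.columns if groups[s] == lab_lo]
    if len(cols_hi) < 2 or len(cols_lo) < 2:
        raise ValueError("need at least 2 samples per group")

    disp = estimate_common_dispersion(
        GeneCountTable(
            sub.counts.loc[tested_mask], sub.samples
        ),
        groups,
    ).common_dispersion

    mean_hi = norm[cols_hi].mean(axis=1).to_numpy()
    mean_lo = norm[cols_lo].mean(axis=1).to_numpy()
    log2fc = np.log2(
        (mean_hi + LOG2FC_PSEUDOCOUNT) / (mean_lo + LOG2FC_PSEUDOCOUNT)
    )

    arr_hi = norm[cols_hi].to_numpy()
    arr_lo = norm[cols_lo].to_numpy()
    pvals = np.full(len(norm), np.nan)
    for i in np.flatnonzero(tested_mask):
        pvals[i] = nb_exact_test(arr_hi[i], arr_lo[i], disp)

    qvals = np.full(len(norm), np.nan)
    qvals[tested_mask] = bh_adjust(pvals[tested_mask])
    significant = np.zeros(len(norm), dtype=bool)
    significant[tested_mask] = qvals[tested_mask] < thresholds.fdr_cutoff

    return pd.DataFrame(
        {
            "gene_id": sub.counts.index,
            "log2fc": log2fc,
            "pvalue": pvals,
            "qvalue": qvals,
            "significant": significant,
            "mean_norm_count": (mean_hi + mean_lo) / 2.0,
            "tested": tested_mask,
        }
    ).reset_index(drop=True)
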