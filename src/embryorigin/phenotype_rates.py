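"""Embryo development rates and paired arm comparisons.

Cleavage rate = cleaved / oocytes inseminated; blastocyst rate =
blastocysts / cleaved embryos (the denominator is cleaved, not
inseminated).  Arm comparisons (treated vs control, or high- vs
low-fertility sires) are paired by IVF replicate: the percent change is
computed on replicate-mean rates and significance comes from a paired
t-test on the replicate rate pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import EmbryoTally
from .qpcr_validation import paired_t_test


class RateUndefinedError(ZeroDivisionError):
    """A rate whose denominator is zero; the message names the rate."""


@dataclass(frozen=True)
class RateResult:
    """Development rates for one replicate arm.

    ``blastocyst_rate`` raises :class:`RateUndefinedError` when no embryo
    cleaved (the denominator is the cleaved count).
    """

    arm: str
    replicate: int
    n_oocytes: int
    n_cleaved: int
    n_blastocyst: int

    @property
    def cleavage_rate(self) -> float:
        if self.n_oocytes == 0:
            raise RateUndefinedError(
                f"cleavage_rate undefined: no oocytes in arm {self.arm!r}"
            )
        return self.n_cleaved / self.n_oocytes

    @property
    def blastocyst_rate(self) -> float:
        if self.n_cleaved == 0:
            raise RateUndefinedError(
                f"blastocyst_rate undefined: no cleaved embryos in arm "
                f"{self.arm!r}"
            )
        return self.n_blastocyst / self.n_cleaved


def compute_rates(tally: EmbryoTally) -> RateResult:
    """Rates for one tally row; denominators are validated lazily so a
    zero-cleavage arm still reports its cleavage rate."""
    return RateResult(tally.arm, tally.replicate, tally.n_oocytes,
                      tally.n_cleaved, tally.n_blastocyst)


@dataclass(frozen=True)
class ArmComparison:
    """Replicate-paired comparison of two arms on one rate."""

    rate: str
    percent_change: float          # 100 * (mean_t - mean_c) / mean_c
    percentage_point_change: float  # 100 * (mean_t - mean_c)
    mean_treated: float
    mean_control: float
    t_statistic: float
    p_value: float
    n_replicates: int


def compare_arms_paired(
    treated: list[RateResult],
    control: list[RateResult],
    rate: str = "blastocyst",
) -> ArmComparison:
    """Compare two replicate-matched arm series on cleavage or blastocyst
    rate.

    percent_change is the relative increase of the treated replicate-mean
    rate over the control mean; the percentage-point difference is
    reported alongside.  Significance is a two-sided paired t-test on the
    per-replicate rate pairs.
    """
    if rate not in ("cleavage", "blastocyst"):
        raise ValueError(f"rate must be 'cleavage' or 'blastocyst', got {rate!r}")
    if len(treated) != len(control) or len(treated) < 2:
        raise ValueError("need equal-length arm lists with >= 2 replicates")
    t_sorted = sorted(treated, key=lambda r: r.replicate)
    c_sorted = sorted(control, key=lambda r: r.replicate)
    if [r.replicate for r in t_sorted] != [r.replicate for r in c_sorted]:
        raise ValueError("replicate sets of the two arms do not match")
    attr = f"{rate}_rate"
    x = np.array([getattr(r, attr) for r in t_sorted])
    y = np.array([getattr(r, attr) for r in c_sorted])
    mean_t, mean_c = float(x.mean()), float(y.mean())
    if mean_c == 0:
        raise RateUndefinedError("percent change undefined: control mean is 0")
    t_stat, p = paired_t_test(x, y)
    return ArmComparison(
        rate=rate,
        percent_change=100.0 * (mean_t - mean_c) / mean_c,
        percentage_point_change=100.0 * (mean_t - mean_c),
        mean_treated=mean_t,
        mean_control=mean_c,
        t_statistic=t_stat,
        p_value=p,
        n_replicates=len(t_sorted),
    )
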