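"""Statistical validation of measured data.

Two checks mirror the field campaign's technical validation.  First, measured
oxygen concentrations are compared against the conventional well-mixed
atmosphere value of 20.946% by one-sample t-tests, stratified by season and
year, with t-based 95% confidence intervals for the stratum means.  A
significant departure in every stratum is the evidence that near-surface
oxygen concentration on the plateau is not the textbook constant.  Second,
field-measured fractional vegetation coverage is regressed on the co-located
remote-sensing product to check that satellite vegetation data can stand in
for ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
import math
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .calibration import CalibrationFit, InstrumentCalibrator
from .errors import InsufficientDataError, ParameterError
from .measurements import MeasurementTable

__all__ = [
    "REFERENCE_OXYGEN",
    "TTestResult",
    "SummaryStats",
    "one_sample_ttest",
    "summarize_by_stratum",
    "regress_validation",
]

#: Conventional volumetric oxygen concentration of well-mixed dry air (%).
REFERENCE_OXYGEN = 20.946


class TTestResult(NamedTuple):
    t_statistic: float
    p_value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class SummaryStats:
    """One season-by-year stratum: sample size, moments and t-test vs mu0.

    ``std`` is the sample standard deviation (n-1 denominator); the confidence
    interval is the t-based 95% interval for the stratum mean.  Test fields
    are None for strata with a single record.
    """

    season: str
    year: int
    n: int
    mean: float
    std: Optional[float] = None
    t_statistic: Optional[float] = None
    p_value: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


def one_sample_ttest(values: Sequence[float], mu0: float = REFERENCE_OXYGEN) -> TTestResult:
    """Two-sided one-sample t-test of the mean against ``mu0``, with the
    t-based 95% confidence interval of the mean.

    Raises :class:`InsufficientDataError` for fewer than 2 values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("one-sample t-test needs at least 2 values")
    if not np.isfinite(v).all():
        raise ParameterError("non-finite values in sample")
    if v.std(ddof=1) == 0.0:
        # Degenerate sample: zero spread makes the statistic 0/0 (mean == mu0)
        # or infinite; handle directly rather than via the t distribution.
        mean = float(v.mean())
        if mean == mu0:
            return TTestResult(t_statistic=0.0, p_value=1.0, ci_low=mean, ci_high=mean)
        t = math.inf if mean > mu0 else -math.inf
        return TTestResult(t_statistic=t, p_value=0.0, ci_low=mean, ci_high=mean)
    res = stats.ttest_1samp(v, popmean=mu0)
    ci = res.confidence_interval(0.95)
    return TTestResult(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
    )


def summarize_by_stratum(
    table: MeasurementTable, mu0: float = REFERENCE_OXYGEN
) -> list[SummaryStats]:
    """Season-by-year summary of measured oxygen concentration.

    Records are grouped by (season, year) using the month rule (6-8 summer,
    11-2 winter); records outside the two seasons or without a timestamp or
    oxygen value are excluded.  Rows are sorted summer first, then by year.
    Single-record strata are reported without std or test fields.
    """
    groups: dict[tuple[str, int], list[float]] = {}
    for rec in table:
        if rec.season is None or rec.oxygen_concentration is None or rec.timestamp is None:
            continue
        key = (rec.season, rec.timestamp.year)
        groups.setdefault(key, []).append(rec.oxygen_concentration)

    out = []
    for (season, year), vals in sorted(
        groups.items(), key=lambda kv: (kv[0][0] != "summer", kv[0][1])
    ):
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            out.append(SummaryStats(season=season, year=year, n=int(v.size), mean=float(v.mean())))
            continue
        tt = one_sample_ttest(v, mu0)
        out.append(
            SummaryStats(
                season=season,
                year=year,
                n=int(v.size),
                mean=float(v.mean()),
                std=float(v.std(ddof=1)),
                t_statistic=tt.t_statistic,
                p_value=tt.p_value,
                ci_low=tt.ci_low,
                ci_high=tt.ci_high,
            )
        )
    return out


def regress_validation(
    measured: Sequence[float], reference: Sequence[float]
) -> CalibrationFit:
    """OLS of field-measured values on a co-located reference (remote-sensing)
    series, with R² and the two-sided slope-test p-value.

    Raises :class:`ParameterError` on length mismatch and
    :class:`InsufficientDataError` below 3 pairs.
    """
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.size != r.size:
        raise ParameterError("measured and reference series must have equal length")
    return InstrumentCalibrator(source_group="reference", target_group="measured").fit(r, m).to_fit()
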