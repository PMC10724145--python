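"""Cross-calibration of oxygen-meter instrument groups.

Four groups of meters were in service over the campaign years (A: the 2017
CY-12C set, B: the 2018-2020 TD400 set, C: the 2021 replacement set, D: the
2022 set).  Simultaneous side-by-side readings at shared points give pairwise
linear relationships between groups; multi-year data are harmonized by
regressing the target group's readings on the source group's and substituting
each source reading into the fitted line.  Group B (the largest sample,
2018-2020) is the conventional harmonization target.

Coefficients always come from session data — the pairwise equations are not
published, only their goodness of fit (R² of 1.0 among the TD400 groups,
above 0.7 between the CY-12C group and the others).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import CalibrationConfigError, InsufficientDataError, ParameterError
from .measurements import MeasurementTable

__all__ = [
    "CalibrationSession",
    "CalibrationFit",
    "InstrumentCalibrator",
    "fit_pairwise_calibration",
    "apply_calibration",
]


@dataclass(frozen=True)
class CalibrationSession:
    """Simultaneous readings at one point, one mean value per instrument group."""

    point_id: str
    readings: Mapping[str, float]  # group label -> oxygen concentration (%)

    def __post_init__(self) -> None:
        if len(self.readings) < 2:
            raise ValueError("a calibration session needs readings from at least two groups")


@dataclass(frozen=True)
class CalibrationFit:
    """Linear map from one group's readings to another's: target = slope*source + intercept."""

    source_group: str
    target_group: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("calibration fit needs n >= 3 sessions")
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")

    def apply(self, value):
        return self.slope * np.asarray(value, dtype=float) + self.intercept

    def inverted(self) -> "CalibrationFit":
        """Algebraic inverse (source = (target - intercept)/slope), groups swapped."""
        if self.slope == 0:
            raise ParameterError("cannot invert a zero-slope calibration")
        return replace(
            self,
            source_group=self.target_group,
            target_group=self.source_group,
            slope=1.0 / self.slope,
            intercept=-self.intercept / self.slope,
        )


class InstrumentCalibrator(TransformerMixin, BaseEstimator):
    """OLS harmonization line between two instrument groups (sklearn-style).

    ``fit(X, y)`` regresses target readings ``y`` on source readings ``X``
    (shape (n,) or (n, 1)); ``transform(X)`` converts source readings to the
    target standard.
    """

    def __init__(self, source_group: str = "A", target_group: str = "B"):
        self.source_group = source_group
        self.target_group = target_group

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.size != y.size:
            raise ParameterError("source and target readings must have equal length")
        if x.size < 3:
            raise InsufficientDataError(
                f"need >= 3 paired sessions for {self.source_group}->{self.target_group}, "
                f"got {x.size}"
            )
        if np.ptp(x) == 0:
            raise InsufficientDataError("source readings are constant; slope undefined")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = min(float(res.rvalue) ** 2, 1.0)
        self.p_value_ = float(res.pvalue)
        self.n_ = int(x.size)
        return self

    def transform(self, X):
        x = np.asarray(X, dtype=float)
        return self.slope_ * x + self.intercept_

    def to_fit(self) -> CalibrationFit:
        return CalibrationFit(
            source_group=self.source_group,
            target_group=self.target_group,
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            n=self.n_,
            p_value=self.p_value_,
        )


def fit_pairwise_calibration(
    sessions: Sequence[CalibrationSession], source: str, target: str
) -> CalibrationFit:
    """Fit target readings on source readings over sessions containing both groups.

    Raises :class:`InsufficientDataError` with fewer than 3 complete pairs.
    """
    pairs = [
        (s.readings[source], s.readings[target])
        for s in sessions
        if source in s.readings and target in s.readings
    ]
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"only {len(pairs)} sessions contain both groups {source} and {target}"
        )
    x, y = zip(*pairs)
    return InstrumentCalibrator(source, target).fit(x, y).to_fit()


def apply_calibration(
    table: MeasurementTable, fits: Sequence[CalibrationFit], target: str = "B"
) -> MeasurementTable:
    """Convert every record's oxygen reading to the target group's standard.

    Records already in the target group pass through unchanged; every other
    group present must have a fit to ``target`` (else
    :class:`CalibrationConfigError`).  Converted records carry an in-memory
    provenance note and are re-labeled to the target group.
    """
    by_source = {f.source_group: f for f in fits if f.target_group == target}
    groups_present = {r.instrument_group for r in table if r.instrument_group is not None}
    missing = sorted(g for g in groups_present if g != target and g not in by_source)
    if missing:
        raise CalibrationConfigError(
            f"no calibration fit to group {target} for group(s): {', '.join(missing)}"
        )
    out = []
    for rec in table:
        g = rec.instrument_group
        if g is None or g == target or rec.oxygen_concentration is None:
            out.append(rec)
            continue
        f = by_source[g]
        new_oc = float(f.apply(rec.oxygen_concentration))
        out.append(
            replace(
                rec,
                oxygen_concentration=new_oc,
                instrument_group=target,
                calibration_note=(
                    f"{g}->{target}: OC' = {f.slope:.6g}*OC + {f.intercept:.6g} "
                    f"(was {rec.oxygen_concentration})"
                ),
            )
        )
    return table.replace_records(out)
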