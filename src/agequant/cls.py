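"""Chronological-lifespan analysis.

Colony-forming-unit (CFU) concentrations are estimated from serial-dilution
plating counts by Poisson maximum likelihood, converted into relative
viability curves (percent of the Day-0 estimate), and survival tables from
organismal lifespan assays are compared with Kaplan-Meier estimates and the
two-group log-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EstimationError,
    InvalidInputError,
    InvalidParameterError,
    UndefinedRatioError,
)

DEFAULT_MAX_COUNTABLE = 400


@dataclass(frozen=True)
class PlateCount:
    """One plated dilution: ``colony_count`` colonies observed after plating
    ``plated_volume_ml`` of a ``dilution_factor``-fold diluted culture."""

    dilution_factor: float
    plated_volume_ml: float
    colony_count: int
    countable: bool = True

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise InvalidParameterError(
                f"dilution_factor must be >= 1, got {self.dilution_factor}"
            )
        if self.plated_volume_ml <= 0:
            raise InvalidParameterError(
                f"plated_volume_ml must be positive, got {self.plated_volume_ml}"
            )
        if self.colony_count < 0 or self.colony_count != int(self.colony_count):
            raise InvalidInputError(
                f"colony_count must be a non-negative integer, got {self.colony_count}"
            )

    @property
    def exposure_ml(self) -> float:
        """Effective volume of undiluted culture represented by this plate."""
        return self.plated_volume_ml / self.dilution_factor


@dataclass
class DilutionPlatingRecord:
    """All plates for one timepoint of one biological replicate."""

    timepoint_day: int
    replicate_id: str
    plates: list[PlateCount] = field(default_factory=list)


@dataclass(frozen=True)
class CfuEstimate:
    """Poisson MLE of the CFU concentration with an exact confidence interval."""

    cfu_per_ml_hat: float
    ci_low: float
    ci_high: float
    n_plates_used: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.cfu_per_ml_hat <= self.ci_high):
            raise InvalidInputError("CI must bracket the point estimate")


@dataclass
class ViabilityCurve:
    """Cross-replicate viability summary; ``per_replicate`` keeps the raw
    percentages used for the mean/SE."""

    summary: pd.DataFrame  # columns: timepoint_day, percent_mean, se, n_replicates
    per_replicate: pd.DataFrame  # columns: timepoint_day, replicate_id, percent


def estimate_cfu_mle(
    record: DilutionPlatingRecord,
    *,
    max_countable: int = DEFAULT_MAX_COUNTABLE,
    alpha: float = 0.05,
) -> CfuEstimate:
    """Estimate CFU/mL by Poisson maximum likelihood over countable plates.

    Model: the count on plate *j* is Poisson with mean
    ``lambda * v_j / d_j`` where *v_j* is the plated volume and *d_j* the
    dilution factor. The MLE is the total count divided by the total
    exposure, ``sum(y) / sum(v/d)``. Plates flagged uncountable or with more
    than ``max_countable`` colonies (merged colonies break the count model)
    are excluded. The confidence interval is the exact (Garwood) Poisson
    interval on the summed count, rescaled by the total exposure.
    """
    usable = [
        p
        for p in record.plates
        if p.countable and p.colony_count <= max_countable
    ]
    if not usable:
        raise EstimationError(
            f"no countable plates for day {record.timepoint_day}, "
            f"replicate {record.replicate_id}"
        )
    total_count = sum(p.colony_count for p in usable)
    total_exposure = sum(p.exposure_ml for p in usable)
    if total_exposure <= 0:
        raise InvalidInputError("total exposure (sum of v/d) must be positive")

    lam_hat = total_count / total_exposure
    if total_count == 0:
        count_low = 0.0
    else:
        count_low = 0.5 * stats.chi2.ppf(alpha / 2, 2 * total_count)
    count_high = 0.5 * stats.chi2.ppf(1 - alpha / 2, 2 * total_count + 2)
    return CfuEstimate(
        cfu_per_ml_hat=lam_hat,
        ci_low=count_low / total_exposure,
        ci_high=count_high / total_exposure,
        n_plates_used=len(usable),
    )


def viability_curve(
    estimates: Mapping[tuple[int, str], CfuEstimate],
    day0: int = 0,
) -> ViabilityCurve:
    """Build a relative-viability curve from per-timepoint/replicate estimates.

    Each replicate is normalised to its own Day-0 estimate (100 percent),
    then the per-timepoint mean and standard error are taken across
    replicates.
    """
    replicates = sorted({rep for (_, rep) in estimates})
    if not replicates:
        raise InvalidInputError("no estimates supplied")
    rows = []
    for rep in replicates:
        key0 = (day0, rep)
        if key0 not in estimates:
            raise InvalidInputError(f"replicate {rep!r} has no Day-{day0} estimate")
        baseline = estimates[key0].cfu_per_ml_hat
        if baseline <= 0:
            raise UndefinedRatioError(
                f"Day-{day0} estimate is zero for replicate {rep!r}"
            )
        for (day, r), est in estimates.items():
            if r != rep:
                continue
            rows.append(
                {
                    "timepoint_day": day,
                    "replicate_id": rep,
                    "percent": 100.0 * est.cfu_per_ml_hat / baseline,
                }
            )
    per_rep = pd.DataFrame(rows).sort_values(
        ["timepoint_day", "replicate_id"], ignore_index=True
    )

    def _se(x: pd.Series) -> float:
        if len(x) < 2:
            return 0.0
        return float(x.std(ddof=1) / math.sqrt(len(x)))

    summary = (
        per_rep.groupby("timepoint_day")["percent"]
        .agg(percent_mean="mean", se=_se, n_replicates="size")
        .reset_index()
    )
    return ViabilityCurve(summary=summary, per_replicate=per_rep)


# ---------------------------------------------------------------------------
# Survival analysis (organismal lifespan assays)
# ---------------------------------------------------------------------------


def _validate_survival_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"time", "event", "group"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidInputError(f"survival table missing columns: {sorted(missing)}")
    if (table["time"] <= 0).any():
        raise InvalidInputError("survival times must be positive")
    return table


def kaplan_meier(table: pd.DataFrame, group: Optional[str] = None) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a frame with columns ``time``, ``n_at_risk``, ``n_events``,
    ``survival``. Censoring at an event time is ranked after the event
    (the censored individual is still at risk at that time).
    """
    _validate_survival_table(table)
    sub = table if group is None else table[table["group"] == group]
    if len(sub) == 0:
        raise InvalidInputError(f"no records for group {group!r}")
    times = np.asarray(sub["time"], dtype=float)
    events = np.asarray(sub["event"], dtype=bool)
    event_times = np.unique(times[events])
    rows = []
    surv = 1.0
    for t in event_times:
        n_risk = int(np.sum(times >= t))
        n_ev = int(np.sum((times == t) & events))
        surv *= 1.0 - n_ev / n_risk
        rows.append(
            {"time": t, "n_at_risk": n_risk, "n_events": n_ev, "survival": surv}
        )
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def median_lifespan(table: pd.DataFrame, group: str) -> Optional[float]:
    """Smallest time at which the Kaplan-Meier estimate drops to <= 0.5.

    Returns ``None`` (undefined-median signal) when the survival curve never
    reaches 0.5 within the observation window.
    """
    km = kaplan_meier(table, group)
    crossed = km[km["survival"] <= 0.5]
    if len(crossed) == 0:
        return None
    return float(crossed["time"].iloc[0])


def logrank_test(
    table: pd.DataFrame, group_a: str, group_b: str
) -> tuple[float, float]:
    """Two-group log-rank test.

    Sums observed-minus-expected events in group A over distinct event
    times, with the hypergeometric variance at each time (ties handled by
    the standard variance term). Censored records contribute to risk sets
    only. Returns ``(chi_square, p_value)`` with p from chi-square(1).
    """
    _validate_survival_table(table)
    sub = table[table["group"].isin([group_a, group_b])]
    if group_a == group_b or sub["group"].nunique() < 2:
        raise InvalidInputError("log-rank requires two distinct non-empty groups")
    times = np.asarray(sub["time"], dtype=float)
    events = np.asarray(sub["event"], dtype=bool)
    in_a = np.asarray(sub["group"] == group_a)
    if not events.any():
        raise InvalidInputError("log-rank requires at least one event")

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int((events & (times == t)).sum())
        d_a = int((events & (times == t) & in_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def survival_table(
    times: Sequence[float], events: Sequence[bool], groups: Sequence[str]
) -> pd.DataFrame:
    """Assemble and validate a survival table from parallel sequences."""
    table = pd.DataFrame(
        {
            "time": np.asarray(times, dtype=float),
            "event": np.asarray(events, dtype=bool),
            "group": list(groups),
        }
    )
    return _validate_survival_table(table)
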