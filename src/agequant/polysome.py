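"""Polysome-profile quantification and per-fraction mRNA distribution.

An A254 trace along a sucrose gradient is segmented into free-subunit,
monosome (80S) and polysome regions; areas under the baseline-subtracted
curve give the polysome/monosome ratio (P/M, translational efficiency) and
the ribosome content (P+M, translational capacity). A companion statistic
converts per-fraction qPCR Ct values into the percentage of an mRNA found
in each gradient fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    InvalidInputError,
    SegmentationError,
    UndefinedRatioError,
)

FREE_SUBUNITS = "free_subunits"
MONOSOME = "monosome"


@dataclass
class PolysomeTrace:
    sample_id: str
    condition: str
    position: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.position.shape != self.absorbance.shape:
            raise InvalidInputError("position and absorbance must match in length")
        if len(self.position) < 100:
            raise InvalidInputError("trace must contain at least 100 points")
        if not np.all(np.diff(self.position) > 0):
            raise InvalidInputError("positions must be strictly increasing")


@dataclass
class Region:
    label: str
    start: float
    end: float


@dataclass
class PeakSegmentation:
    regions: list[Region]
    baseline_value: float

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if labels.count(MONOSOME) != 1:
            raise InvalidInputError("exactly one monosome region required")
        for a, b in zip(self.regions, self.regions[1:]):
            if b.start < a.end:
                raise InvalidInputError("regions must be ordered and non-overlapping")

    @property
    def monosome(self) -> Region:
        return next(r for r in self.regions if r.label == MONOSOME)


@dataclass
class RibosomeMetrics:
    monosome_auc: float
    polysome_auc_total: float
    pm_ratio: Optional[float]
    ribosome_content: float
    per_region: dict[str, float] = field(default_factory=dict)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    return np.convolve(np.pad(y, window // 2, mode="edge"), kernel, mode="valid")[
        : len(y)
    ]


def segment_trace(
    trace: PolysomeTrace,
    manual_boundaries: Optional[Sequence[tuple[str, float, float]]] = None,
    smooth_window: int = 5,
    prominence_frac: float = 0.05,
) -> PeakSegmentation:
    """Partition a trace into free-subunit / monosome / polysome regions.

    With ``manual_boundaries`` (label, start, end) the regions are validated
    and adopted as-is. Otherwise the trace is smoothed, local maxima above a
    prominence threshold are detected, the first peak (cluster) is labelled
    free subunits, the second monosome, and subsequent peaks polysome_2..k;
    boundaries sit at the inter-peak local minima. The scalar baseline is
    the absorbance at the local minimum on the trailing side of the
    monosome peak.
    """
    x, y = trace.position, trace.absorbance

    if manual_boundaries is not None:
        regions = [Region(lbl, float(s), float(e)) for lbl, s, e in manual_boundaries]
        seg = PeakSegmentation(regions=regions, baseline_value=0.0)
        mono = seg.monosome
        sel = (x >= mono.end - 0.02 * np.ptp(x)) & (x <= mono.end + 0.02 * np.ptp(x))
        baseline = float(np.min(y[sel])) if sel.any() else float(np.interp(mono.end, x, y))
        seg.baseline_value = baseline
        return seg

    smoothed = _moving_average(y, smooth_window)
    span = float(np.ptp(smoothed))
    if span <= 0:
        raise SegmentationError("flat trace: no peaks to segment")
    peaks, _ = find_peaks(smoothed, prominence=prominence_frac * span)
    if len(peaks) < 2:
        raise SegmentationError(
            f"found {len(peaks)} peak(s); need free-subunit and monosome peaks "
            "(supply manual boundaries)"
        )

    # inter-peak valleys as boundaries
    valleys = []
    for a, b in zip(peaks, peaks[1:]):
        valleys.append(a + int(np.argmin(smoothed[a : b + 1])))
    bounds = [0] + valleys + [len(x) - 1]

    labels = [FREE_SUBUNITS, MONOSOME] + [
        f"polysome_{k}" for k in range(2, len(peaks))
    ]
    regions = [
        Region(lbl, float(x[bounds[i]]), float(x[bounds[i + 1]]))
        for i, lbl in enumerate(labels)
    ]
    # trailing valley of the monosome peak; median over a small window keeps
    # the estimate unbiased under measurement noise (a raw argmin is biased low)
    mono_end_idx = bounds[2]
    k = max(smooth_window, len(y) // 50)
    lo, hi = max(mono_end_idx - k, 0), min(mono_end_idx + k + 1, len(y))
    baseline = float(np.median(y[lo:hi]))
    return PeakSegmentation(regions=regions, baseline_value=baseline)


def integrate_auc(
    trace: PolysomeTrace, segmentation: PeakSegmentation
) -> RibosomeMetrics:
    """Trapezoidal AUC per region after baseline subtraction.

    M is the monosome AUC, P the sum of all polysome AUCs; the free-subunit
    region is excluded from both. P/M is undefined (None) when M = 0.
    """
    x, y = trace.position, trace.absorbance
    above = np.clip(y - segmentation.baseline_value, 0.0, None)
    per_region: dict[str, float] = {}
    for region in segmentation.regions:
        sel = (x >= region.start) & (x <= region.end)
        if sel.sum() < 2:
            per_region[region.label] = 0.0
            continue
        per_region[region.label] = float(np.trapezoid(above[sel], x[sel]))
    monosome_auc = per_region.get(MONOSOME, 0.0)
    polysome_total = sum(
        a for lbl, a in per_region.items() if lbl.startswith("polysome")
    )
    pm = polysome_total / monosome_auc if monosome_auc > 0 else None
    return RibosomeMetrics(
        monosome_auc=monosome_auc,
        polysome_auc_total=polysome_total,
        pm_ratio=pm,
        ribosome_content=polysome_total + monosome_auc,
        per_region=per_region,
    )


def relative_content(
    sample_metrics: RibosomeMetrics, control_metrics: RibosomeMetrics
) -> float:
    """Ribosome content (P+M) of a sample relative to a control run."""
    if control_metrics.ribosome_content <= 0:
        raise UndefinedRatioError("control ribosome content is zero")
    return sample_metrics.ribosome_content / control_metrics.ribosome_content


def fraction_distribution(cts: Sequence[Optional[float]]) -> np.ndarray:
    """Percentage of an mRNA in each gradient fraction from qPCR Ct values.

    For detected fractions, dCT_f = CT_max - CT_f (CT_max is the global
    maximum over detected fractions) and the relative amount is 2**dCT_f;
    undetected fractions (None/NaN) contribute zero. Percentages are the
    relative amounts normalised to sum to 100.
    """
    arr = np.array(
        [np.nan if c is None else float(c) for c in cts], dtype=float
    )
    if arr.size < 2:
        raise InvalidInputError("need at least 2 fractions")
    detected = np.isfinite(arr)
    if not detected.any():
        raise InvalidInputError("all fractions undetected")
    ct_max = np.max(arr[detected])
    rel = np.zeros_like(arr)
    rel[detected] = 2.0 ** (ct_max - arr[detected])
    return 100.0 * rel / rel.sum()
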