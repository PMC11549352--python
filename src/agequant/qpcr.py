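"""Relative expression quantification by the comparative-Ct (ddCt) method.

Technical replicate Ct values are averaged on the Ct scale, the target is
normalised to a reference gene (dCt), conditions are normalised to a
control condition (ddCt), and fold change is 2**(-ddCt). Amplification
efficiency is assumed to be 100% (one doubling per cycle). Biological
replicates are aggregated on the log2-fold scale with the standard error
taken across replicates; with a single biological replicate the SE is
propagated from the technical-replicate SDs by quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidInputError


@dataclass
class CtMeasurement:
    """Ct values (technical replicates) for one target in one sample."""

    sample_id: str
    condition: str
    target_id: str
    replicate_cts: list[float]
    is_reference: bool = False

    def __post_init__(self) -> None:
        cts = [c for c in self.replicate_cts if math.isfinite(c)]
        if not cts:
            raise InvalidInputError(
                f"measurement {self.sample_id}/{self.target_id} has no finite Ct"
            )
        self.replicate_cts = list(self.replicate_cts)

    @property
    def mean_ct(self) -> float:
        return float(np.mean([c for c in self.replicate_cts if math.isfinite(c)]))

    @property
    def sd_ct(self) -> float:
        cts = [c for c in self.replicate_cts if math.isfinite(c)]
        return float(np.std(cts, ddof=1)) if len(cts) > 1 else 0.0

    @property
    def n_ct(self) -> int:
        return sum(1 for c in self.replicate_cts if math.isfinite(c))


@dataclass(frozen=True)
class FoldChange:
    target_id: str
    condition: str
    control_condition: str
    log2_fold: float
    se_log2: float
    n_biological: int = 1

    @property
    def fold(self) -> float:
        return 2.0**self.log2_fold


def _pair_by_sample(
    target: Sequence[CtMeasurement], reference: Sequence[CtMeasurement]
) -> dict[str, list[tuple[CtMeasurement, CtMeasurement]]]:
    """Pair target/reference measurements sample-by-sample, grouped by
    condition."""
    ref_by_sample = {m.sample_id: m for m in reference}
    paired: dict[str, list[tuple[CtMeasurement, CtMeasurement]]] = {}
    for m in target:
        if m.sample_id not in ref_by_sample:
            raise InvalidInputError(
                f"sample {m.sample_id!r} has no reference-gene measurement"
            )
        paired.setdefault(m.condition, []).append((m, ref_by_sample[m.sample_id]))
    return paired


def delta_delta_ct(
    target: Sequence[CtMeasurement],
    reference: Sequence[CtMeasurement],
    control_condition: str,
) -> list[FoldChange]:
    """Fold changes of each condition relative to ``control_condition``.

    Per biological sample, dCt = mean(target Ct) - mean(reference Ct);
    ddCt subtracts the mean dCt of the control condition; fold = 2**(-ddCt).
    The control condition itself comes out at fold 1 by construction.
    """
    paired = _pair_by_sample(target, reference)
    if control_condition not in paired:
        raise InvalidInputError(
            f"control condition {control_condition!r} has no measurements"
        )
    dct = {
        cond: np.array([tm.mean_ct - rm.mean_ct for tm, rm in pairs])
        for cond, pairs in paired.items()
    }
    control_dct = float(np.mean(dct[control_condition]))

    results = []
    target_id = target[0].target_id
    for cond, pairs in paired.items():
        log2_folds = -(dct[cond] - control_dct)
        n = len(log2_folds)
        if n > 1:
            se = float(np.std(log2_folds, ddof=1) / math.sqrt(n))
        else:
            # single biological replicate: quadrature over technical SDs of
            # the four Ct means entering ddCt
            terms = []
            for tm, rm in pairs:
                terms += [tm.sd_ct**2 / tm.n_ct, rm.sd_ct**2 / rm.n_ct]
            for tm, rm in paired[control_condition]:
                terms += [tm.sd_ct**2 / tm.n_ct, rm.sd_ct**2 / rm.n_ct]
            se = float(math.sqrt(sum(terms)))
        results.append(
            FoldChange(
                target_id=target_id,
                condition=cond,
                control_condition=control_condition,
                log2_fold=float(np.mean(log2_folds)),
                se_log2=se,
                n_biological=n,
            )
        )
    return results
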