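"""Calling RNA-bound proteins from pulldown proteomics intensity matrices.

The strategy follows the bespoke scheme used for RNA-centric pulldown
screens: a detection-based presence filter, imputation of residual missing
values with 1, a variance-stabilising log transform with per-sample robust
calibration, a moderated t-test with empirical-Bayes variance shrinkage
against the deletion-control strain, Benjamini-Hochberg FDR per contrast,
and a stringent joint FDR / log2 fold-change cut-off combined across
contrasts with an OR rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import CalibrationError, InvalidInputError

DEFAULT_FDR_MAX = 0.005
DEFAULT_LFC_MIN = 6.5
IMPUTE_VALUE = 1.0


@dataclass
class ProteinQuantMatrix:
    """Proteins x samples intensities (NaN = not identified) plus the
    sample -> (strain, replicate) design."""

    intensities: pd.DataFrame
    design: pd.DataFrame  # columns: sample, strain, replicate

    def __post_init__(self) -> None:
        required = {"sample", "strain", "replicate"}
        if not required <= set(self.design.columns):
            raise InvalidInputError(f"design needs columns {sorted(required)}")
        if set(self.intensities.columns) != set(self.design["sample"]):
            raise InvalidInputError("design samples must match matrix columns")
        if (self.intensities <= 0).any().any():
            raise InvalidInputError("intensities must be positive where present")

    def samples_for(self, strain: str) -> list[str]:
        return list(self.design.loc[self.design["strain"] == strain, "sample"])

    @property
    def strains(self) -> list[str]:
        return list(self.design["strain"].unique())


def load_protein_table(matrix_path, design_path) -> ProteinQuantMatrix:
    """Load a proteins x samples intensity TSV (first column = protein id,
    empty cells = not identified) and a design TSV with columns
    sample/strain/replicate."""
    intensities = pd.read_csv(matrix_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t")
    return ProteinQuantMatrix(intensities=intensities, design=design)


def presence_filter(
    matrix: ProteinQuantMatrix, min_reps: int = 2
) -> ProteinQuantMatrix:
    """Keep proteins identified in >= ``min_reps`` replicates of at least
    one strain; drop the rest (count logged via a warning summary)."""
    keep = pd.Series(False, index=matrix.intensities.index)
    for strain in matrix.strains:
        cols = matrix.samples_for(strain)
        keep |= matrix.intensities[cols].notna().sum(axis=1) >= min_reps
    dropped = int((~keep).sum())
    filtered = matrix.intensities.loc[keep]
    if filtered.empty:
        warnings.warn("presence filter removed every protein", stacklevel=2)
    elif dropped:
        warnings.warn(f"presence filter removed {dropped} protein(s)", stacklevel=2)
    return ProteinQuantMatrix(intensities=filtered, design=matrix.design)


def impute_and_normalize(
    matrix: ProteinQuantMatrix,
    calibrate: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute residual missing values with 1, log2-transform, and apply a
    per-sample robust affine calibration.

    Calibration recentres each sample to the cross-sample median location
    and rescales its spread (median absolute deviation) to the median
    spread, so planted per-sample gain factors cancel while the global log2
    scale is preserved. Returns (normalised log2 matrix, per-sample
    calibration parameters).
    """
    raw = matrix.intensities
    for sample in raw.columns:
        if raw[sample].notna().sum() < 3:
            raise CalibrationError(
                f"sample {sample!r} has fewer than 3 finite intensities"
            )
    log2 = np.log2(raw.fillna(IMPUTE_VALUE))
    if not calibrate:
        params = pd.DataFrame(
            {"sample": log2.columns, "median": 0.0, "mad": 1.0}
        ).set_index("sample")
        return log2, params

    med = log2.median(axis=0)
    mad = (log2 - med).abs().median(axis=0)
    if (mad <= 0).any():
        bad = list(mad.index[mad <= 0])
        raise CalibrationError(f"zero spread in sample(s) {bad}; cannot rescale")
    target_scale = float(mad.median())
    target_loc = float(med.median())
    normalized = (log2 - med) / mad * target_scale + target_loc
    params = pd.DataFrame(
        {"sample": log2.columns, "median": med.values, "mad": mad.values}
    ).set_index("sample")
    return normalized, params


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match an empirical-Bayes prior (d0, s0^2) to the distribution
    of per-protein sample variances, on the log scale.

    Under the hierarchical model, log(s2) has expectation
    log(s0^2) + digamma(d/2) - log(d/2) - (digamma(d0/2) - log(d0/2)) and
    extra variance trigamma(d0/2) beyond trigamma(d/2); matching the first
    two moments gives the closed-form estimator (d0 = inf when the observed
    spread does not exceed the chi-square expectation).
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 0.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    # invert trigamma(d0/2) = e_var by Newton iteration on f(y)=trigamma(y)-target
    y = 0.5 + 1.0 / e_var  # starting guess from trigamma(x) ~ 1/x
    for _ in range(100):
        tri = float(special.polygamma(1, y))
        deriv = float(special.polygamma(2, y))
        step = (tri - e_var) / deriv
        y = max(y - step, 1e-8)
        if abs(step) < 1e-10 * y:
            break
    d0 = 2.0 * y
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def differential_enrichment(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    contrasts: Sequence[tuple[str, str]],
    d0_override: Optional[float] = None,
) -> pd.DataFrame:
    """Moderated t-test per protein and contrast with BH FDR per contrast.

    Each contrast is (test_strain, reference_strain); the log2 fold-change
    is mean(test) - mean(reference). Per-protein pooled variances are
    shrunk toward an empirical-Bayes prior, s2_mod =
    (d0*s0^2 + d*s2)/(d0 + d), and the t statistic has d0 + d degrees of
    freedom. ``d0_override=0`` reproduces the ordinary two-sample t-test.
    """
    sample_strain = dict(zip(design["sample"], design["strain"]))
    frames = []
    for test, ref in contrasts:
        cols_a = [s for s in normalized.columns if sample_strain.get(s) == test]
        cols_b = [s for s in normalized.columns if sample_strain.get(s) == ref]
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise InvalidInputError(
                f"contrast {test} vs {ref} needs >= 2 replicates per arm"
            )
        a = normalized[cols_a].to_numpy(dtype=float)
        b = normalized[cols_b].to_numpy(dtype=float)
        na, nb = a.shape[1], b.shape[1]
        df_resid = na + nb - 2
        if df_resid <= 0:
            raise InvalidInputError("zero residual degrees of freedom")
        diff = a.mean(axis=1) - b.mean(axis=1)
        ssq = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
            (b - b.mean(axis=1, keepdims=True)) ** 2
        ).sum(axis=1)
        s2 = ssq / df_resid

        if d0_override is not None:
            d0 = float(d0_override)
            s0_sq = 0.0
        else:
            d0, s0_sq = _fit_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_mod = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_mod = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid

        se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
        p = np.clip(p, 0.0, 1.0)
        fdr = multipletests(p, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "protein": normalized.index,
                    "contrast": f"{test}_vs_{ref}",
                    "log2_fc": diff,
                    "moderated_t": t,
                    "df": df_total,
                    "p_value": p,
                    "fdr": fdr,
                    "d0": d0,
                    "s0_sq": s0_sq,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def call_bound(
    results: pd.DataFrame,
    fdr_max: float = DEFAULT_FDR_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> set[str]:
    """Proteins passing FDR <= ``fdr_max`` AND log2FC >= ``lfc_min`` in at
    least one contrast (OR rule across contrasts; thresholds inclusive)."""
    passing = results[(results["fdr"] <= fdr_max) & (results["log2_fc"] >= lfc_min)]
    return set(passing["protein"])
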