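"""Seeded synthetic-data generators for every input the pipelines consume.

Each generator draws all randomness from a single explicit seed (no global
state), returns the simulated data together with a ground-truth record of
the parameters actually used, and emulates the noise structure of the
corresponding assay: Poisson plating counts, multiplicative spatial plate
gradients, Gaussian absorbance bumps over a baseline, Ct measurement noise,
intensity-dependent (missing-not-at-random) proteomics dropout, growth
curves with heteroscedastic noise, and survival times from a Gompertz
hazard with independent censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .chirp import ProteinQuantMatrix
from .cls import DilutionPlatingRecord, PlateCount, survival_table
from .errors import InvalidParameterError
from .growth import MODEL_FORMS, GrowthCurve
from .polysome import PolysomeTrace
from .sga import ColonyPlate


@dataclass
class SimulationConfig:
    """Seed plus a free-form parameter block for one generator call."""

    seed: int
    params: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Serial-dilution plating counts
# ---------------------------------------------------------------------------


def simulate_dilution_counts(
    true_cfu_per_ml: Mapping[int, float],
    dilutions: Sequence[float],
    plated_volume_ml: float,
    plates_per_dilution: int = 2,
    seed: int = 0,
    replicate_id: str = "rep1",
) -> tuple[list[DilutionPlatingRecord], pd.DataFrame]:
    """Poisson plating counts over a dilution series, one record per
    timepoint. Counts on each plate are independent Poisson with mean
    ``cfu * volume / dilution``."""
    if plated_volume_ml <= 0:
        raise InvalidParameterError("plated volume must be positive")
    if any(d < 1 for d in dilutions):
        raise InvalidParameterError("dilution factors must be >= 1")
    if plates_per_dilution < 1:
        raise InvalidParameterError("plates_per_dilution must be >= 1")
    for day, cfu in true_cfu_per_ml.items():
        if not np.isfinite(cfu) or cfu < 0:
            raise InvalidParameterError(f"invalid CFU concentration at day {day}")

    rng = np.random.default_rng(seed)
    records = []
    truth_rows = []
    for day in sorted(true_cfu_per_ml):
        cfu = true_cfu_per_ml[day]
        plates = []
        for dilution in dilutions:
            mean = cfu * plated_volume_ml / dilution
            counts = rng.poisson(mean, size=plates_per_dilution)
            for c in counts:
                plates.append(
                    PlateCount(
                        dilution_factor=float(dilution),
                        plated_volume_ml=float(plated_volume_ml),
                        colony_count=int(c),
                    )
                )
        records.append(
            DilutionPlatingRecord(
                timepoint_day=day, replicate_id=replicate_id, plates=plates
            )
        )
        truth_rows.append({"timepoint_day": day, "true_cfu_per_ml": cfu})
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Colony-array screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimulation:
    query_plates: list[ColonyPlate]
    control_plates: list[ColonyPlate]
    truth: pd.DataFrame  # columns gene_id, true_gis
    artifact_positions: np.ndarray  # boolean grid of planted small/absent colonies


def _spatial_surface(rows: int, cols: int, amplitude: float) -> np.ndarray:
    """Smooth multiplicative surface: half linear column ramp, half radial
    bowl, centred so the mean factor is ~1."""
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    ramp = jj / max(cols - 1, 1)
    ci, cj = (rows - 1) / 2.0, (cols - 1) / 2.0
    dist = np.sqrt((ii - ci) ** 2 + (jj - cj) ** 2)
    radial = 1.0 - dist / dist.max()
    shape = 0.5 * ramp + 0.5 * radial
    return 1.0 + amplitude * (shape - shape.mean())


def simulate_colony_screen(
    grid_rows: int = 16,
    grid_cols: int = 24,
    n_interactors: int = 0,
    effect_log10: Union[float, Sequence[float]] = 0.0,
    gradient_amplitude: float = 0.0,
    small_colony_rate: float = 0.0,
    seed: int = 0,
    n_repeats: int = 3,
    n_genes: Optional[int] = None,
    size_median_px: float = 500.0,
    size_sigma_log10: float = 0.03,
) -> ScreenSimulation:
    """Query/control colony plates with planted interactions and artefacts.

    Colony sizes are lognormal around ``size_median_px`` times a smooth
    multiplicative spatial surface (fresh orientation-scaled draw per
    plate), times ``10**effect`` for the planted interactor genes on query
    plates only. A fraction ``small_colony_rate`` of library positions is
    replaced with sub-100-px colonies on every control plate (mimicking
    absent/sick library mutants).
    """
    n_positions = grid_rows * grid_cols
    if n_genes is None:
        n_genes = n_positions
    if n_genes > n_positions:
        raise InvalidParameterError("more genes than grid positions")
    if n_interactors > n_genes:
        raise InvalidParameterError("more interactors than genes")
    if not 0 <= small_colony_rate < 1:
        raise InvalidParameterError("small_colony_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    gene_ids = [f"g{k:04d}" for k in range(1, n_genes + 1)]
    flat_map = np.array(gene_ids + [None] * (n_positions - n_genes), dtype=object)
    rng.shuffle(flat_map)
    gene_map = flat_map.reshape(grid_rows, grid_cols)

    effects = np.broadcast_to(
        np.atleast_1d(np.asarray(effect_log10, dtype=float)), (n_interactors,)
    ) if n_interactors else np.empty(0)
    interactors = list(rng.choice(gene_ids, size=n_interactors, replace=False))
    effect_by_gene = dict(zip(interactors, effects))

    artifact = rng.random((grid_rows, grid_cols)) < small_colony_rate
    artifact &= gene_map != None  # noqa: E711  (elementwise comparison)

    sigma_ln = size_sigma_log10 * np.log(10.0)
    query_factor = np.ones((grid_rows, grid_cols))
    for i in range(grid_rows):
        for j in range(grid_cols):
            g = gene_map[i, j]
            if g in effect_by_gene:
                query_factor[i, j] = 10.0 ** effect_by_gene[g]

    def make_plate(role: str, rep: int) -> ColonyPlate:
        surface = _spatial_surface(grid_rows, grid_cols, gradient_amplitude)
        base = size_median_px * np.exp(rng.normal(0.0, sigma_ln, surface.shape))
        grid = base * surface
        if role == "query":
            grid = grid * query_factor
        else:
            grid = grid.copy()
            grid[artifact] = rng.uniform(10.0, 99.0, size=int(artifact.sum()))
        grid[gene_map == None] = np.nan  # noqa: E711
        return ColonyPlate(
            plate_id=f"{role}_r{rep}",
            repeat_id=f"r{rep}",
            query_id=role,
            grid=grid,
            gene_map=gene_map,
        )

    query_plates = [make_plate("query", r) for r in range(1, n_repeats + 1)]
    control_plates = [make_plate("control", r) for r in range(1, n_repeats + 1)]
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_gis": [effect_by_gene.get(g, 0.0) for g in gene_ids],
        }
    )
    return ScreenSimulation(
        query_plates=query_plates,
        control_plates=control_plates,
        truth=truth,
        artifact_positions=artifact,
    )


# ---------------------------------------------------------------------------
# Polysome absorbance traces
# ---------------------------------------------------------------------------


def simulate_polysome_trace(
    region_areas: Mapping[str, float],
    peak_locations: Mapping[str, float],
    peak_widths: Mapping[str, float],
    baseline_level: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 1000,
    x_max: float = 10.0,
    sample_id: str = "sim",
    condition: str = "sim",
) -> tuple[PolysomeTrace, dict[str, Any]]:
    """Sum-of-Gaussians absorbance trace over a flat baseline.

    ``region_areas`` maps region labels (``free_subunits``, ``monosome``,
    ``polysome_2``..) to the analytic area of the corresponding Gaussian
    bump. Adjacent bumps overlapping by more than 1% of their area are
    recorded as a warning in the truth metadata.
    """
    labels = list(region_areas)
    for lbl in labels:
        if region_areas[lbl] <= 0:
            raise InvalidParameterError(f"area for {lbl!r} must be positive")
        if lbl not in peak_locations or lbl not in peak_widths:
            raise InvalidParameterError(f"missing location/width for {lbl!r}")

    order = sorted(labels, key=lambda l: peak_locations[l])
    overlap_warnings = []
    for a, b in zip(order, order[1:]):
        mid = 0.5 * (peak_locations[a] + peak_locations[b])
        tail_a = norm.sf(mid, loc=peak_locations[a], scale=peak_widths[a])
        tail_b = norm.cdf(mid, loc=peak_locations[b], scale=peak_widths[b])
        if tail_a > 0.01 or tail_b > 0.01:
            overlap_warnings.append(f"{a}/{b} overlap beyond 1%")

    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, x_max, n_points)
    y = np.full_like(x, float(baseline_level))
    for lbl in labels:
        y += region_areas[lbl] * norm.pdf(
            x, loc=peak_locations[lbl], scale=peak_widths[lbl]
        )
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)

    trace = PolysomeTrace(
        sample_id=sample_id, condition=condition, position=x, absorbance=y
    )
    truth = {
        "areas": dict(region_areas),
        "locations": dict(peak_locations),
        "widths": dict(peak_widths),
        "baseline_level": float(baseline_level),
        "noise_sd": float(noise_sd),
        "warnings": overlap_warnings,
    }
    return trace, truth


# ---------------------------------------------------------------------------
# Per-fraction qPCR Ct values
# ---------------------------------------------------------------------------


def simulate_fraction_ct(
    true_percentages: Sequence[float],
    ct_at_max_fraction: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[Optional[float]], dict[str, Any]]:
    """Ct per fraction consistent with a known percentage distribution.

    The least-abundant detected fraction gets Ct = ``ct_at_max_fraction``;
    more abundant fractions get proportionally lower Ct (one cycle per
    doubling). Zero-percentage fractions are emitted as undetected (None).
    """
    p = np.asarray(true_percentages, dtype=float)
    if (p < 0).any():
        raise InvalidParameterError("percentages must be non-negative")
    if not (p > 0).any():
        raise InvalidParameterError("at least one percentage must be positive")
    if abs(p.sum() - 100.0) > 1e-6:
        raise InvalidParameterError(
            f"percentages must sum to 100, got {p.sum()!r}"
        )
    rng = np.random.default_rng(seed)
    p_min = p[p > 0].min()
    cts: list[Optional[float]] = []
    for pf in p:
        if pf == 0:
            cts.append(None)
        else:
            ct = ct_at_max_fraction - np.log2(pf / p_min)
            if noise_sd > 0:
                ct += rng.normal(0.0, noise_sd)
            cts.append(float(ct))
    truth = {
        "true_percentages": p.tolist(),
        "ct_at_max_fraction": float(ct_at_max_fraction),
        "noise_sd": float(noise_sd),
    }
    return cts, truth


# ---------------------------------------------------------------------------
# Pulldown proteomics intensity matrices
# ---------------------------------------------------------------------------

DEFAULT_STRAINS = ("wildtype", "overexpression", "deletion_control")


def simulate_protein_matrix(
    n_proteins: int = 300,
    n_bound: int = 0,
    strains: Sequence[str] = DEFAULT_STRAINS,
    replicates: int = 3,
    bound_log2_effect: float = 0.0,
    missing_model: tuple[float, float] = (-np.inf, 0.0),
    seed: int = 0,
    deletion_control: str = "deletion_control",
    base_mean_log2: float = 20.0,
    base_sd_log2: float = 2.0,
    noise_sd_log2: float = 0.5,
) -> tuple[ProteinQuantMatrix, set[str]]:
    """Intensity matrix with planted RNA-bound proteins and MNAR dropout.

    Latent log2 intensities are Gaussian per protein; bound proteins gain
    ``bound_log2_effect`` in every non-deletion strain. Each entry drops
    out with probability ``expit(intercept + slope * latent_log2)``
    (missing-not-at-random; negative slope removes low-intensity values
    preferentially).
    """
    if n_bound > n_proteins:
        raise InvalidParameterError("n_bound exceeds n_proteins")
    if deletion_control not in strains:
        raise InvalidParameterError("strains must include the deletion control")
    if replicates < 2:
        raise InvalidParameterError("need >= 2 replicates per strain")

    rng = np.random.default_rng(seed)
    proteins = [f"P{k:04d}" for k in range(1, n_proteins + 1)]
    bound = set(rng.choice(proteins, size=n_bound, replace=False).tolist())

    samples, strain_of = [], {}
    for strain in strains:
        for r in range(1, replicates + 1):
            s = f"{strain}_{r}"
            samples.append(s)
            strain_of[s] = strain

    base = rng.normal(base_mean_log2, base_sd_log2, size=n_proteins)
    intercept, slope = missing_model
    data = np.empty((n_proteins, len(samples)))
    for j, s in enumerate(samples):
        shift = np.where(
            [
                (p in bound) and (strain_of[s] != deletion_control)
                for p in proteins
            ],
            bound_log2_effect,
            0.0,
        )
        latent = base + shift + rng.normal(0.0, noise_sd_log2, size=n_proteins)
        p_miss = expit(intercept + slope * latent)
        drop = rng.random(n_proteins) < p_miss
        col = 2.0**latent
        col[drop] = np.nan
        data[:, j] = col

    intensities = pd.DataFrame(data, index=proteins, columns=samples)
    design = pd.DataFrame(
        {
            "sample": samples,
            "strain": [strain_of[s] for s in samples],
            "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
        }
    )
    return ProteinQuantMatrix(intensities=intensities, design=design), bound


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------


def simulate_growth_curves(
    model: str,
    A: float,
    mu: float,
    lam: float,
    noise_sd: float = 0.0,
    n_timepoints: int = 100,
    seed: int = 0,
    n_wells: int = 1,
    t_max: Optional[float] = None,
    nu: float = 1.0,
    strain: str = "sim",
    treatment: str = "none",
) -> tuple[list[GrowthCurve], dict[str, Any]]:
    """Growth curves from a named parametric form plus heteroscedastic
    Gaussian noise (noise SD scales from 20% to 100% of ``noise_sd`` as
    biomass approaches capacity)."""
    if model not in MODEL_FORMS:
        raise InvalidParameterError(
            f"unknown model {model!r}; choose from {sorted(MODEL_FORMS)}"
        )
    if A <= 0 or mu <= 0:
        raise InvalidParameterError("A and mu must be positive")
    if lam < 0:
        raise InvalidParameterError("lambda must be non-negative")
    rng = np.random.default_rng(seed)
    if t_max is None:
        t_max = lam + 6.0 * A / mu
    t = np.linspace(0.0, t_max, n_timepoints)
    form = MODEL_FORMS[model]
    clean = form(t, A, mu, lam, nu) if model == "richards" else form(t, A, mu, lam)

    curves = []
    for w in range(1, n_wells + 1):
        y = clean.copy()
        if noise_sd > 0:
            sd = noise_sd * (0.2 + 0.8 * clean / A)
            y = y + rng.normal(0.0, 1.0, size=y.shape) * sd
        curves.append(
            GrowthCurve(
                well_id=f"well_{w}",
                strain=strain,
                treatment=treatment,
                time_h=t,
                biomass=y,
            )
        )
    truth = {
        "model": model, "A": A, "mu": mu, "lambda": lam, "nu": nu,
        "noise_sd": noise_sd,
    }
    return curves, truth


# ---------------------------------------------------------------------------
# Organismal lifespans
# ---------------------------------------------------------------------------


def simulate_lifespans(
    n_per_group: int,
    hazard_params: Mapping[str, tuple[float, float]],
    censor_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Event/censoring tables from a Gompertz hazard h(t) = a * exp(b*t).

    ``hazard_params`` maps group label to (a, b); b = 0 gives an
    exponential hazard. With probability ``censor_rate`` an individual is
    censored at a uniform time before its latent death time.
    """
    if n_per_group < 1:
        raise InvalidParameterError("n_per_group must be >= 1")
    if not 0 <= censor_rate < 1:
        raise InvalidParameterError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    times, events, groups = [], [], []
    for group, (a, b) in hazard_params.items():
        if a <= 0:
            raise InvalidParameterError(f"hazard scale for {group!r} must be positive")
        u = rng.random(n_per_group)
        if b == 0:
            t = -np.log(u) / a
        else:
            t = np.log1p(-b * np.log(u) / a) / b
        censored = rng.random(n_per_group) < censor_rate
        t_obs = np.where(censored, t * rng.random(n_per_group), t)
        t_obs = np.maximum(t_obs, 1e-9)
        times.extend(t_obs.tolist())
        events.extend((~censored).tolist())
        groups.extend([group] * n_per_group)
    table = survival_table(times, events, groups)
    truth = {
        "hazard_params": {g: tuple(v) for g, v in hazard_params.items()},
        "censor_rate": float(censor_rate),
        "n_per_group": int(n_per_group),
    }
    return table, truth
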