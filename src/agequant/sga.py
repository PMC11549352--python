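"""Genome-wide genetic-interaction scoring from arrayed colony-size grids.

The pipeline mirrors high-density colony-array screening practice: artefact
positions are masked using the neutral-control plates, spatial gradients are
removed by 2D moving-median smoothing followed by row/column median
normalisation, loci genetically linked to the query or control markers are
excluded, and genetic interaction scores (GIS) are computed per repeat as
the clipped log10 ratio of median normalised colony sizes (query vs
control), with consensus hit calls requiring a sign-consistent score in a
minimum number of repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyScreenError,
    InvalidInputError,
    InvalidParameterError,
)

DEFAULT_GRID = (16, 24)  # 384 format
SMALL_COLONY_PX = 100
LINKAGE_RADIUS_BP = 250_000
GIS_CLIP = 2.0
DEFAULT_CUTOFF = 0.1
DEFAULT_MIN_REPEATS = 2


@dataclass
class ColonyPlate:
    """One plate image reduced to a grid of colony sizes (pixels).

    ``grid`` holds NaN for absent/excluded positions. ``gene_map`` is an
    object array of the same shape with gene ids (``None`` for empty
    positions).
    """

    plate_id: str
    repeat_id: str
    query_id: str
    grid: np.ndarray
    gene_map: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.gene_map = np.asarray(self.gene_map, dtype=object)
        if self.grid.shape != self.gene_map.shape:
            raise InvalidInputError("grid and gene_map shapes differ")
        if np.nanmin(self.grid, initial=0.0) < 0:
            raise InvalidInputError("colony sizes must be non-negative")

    def copy_with(self, grid: np.ndarray) -> "ColonyPlate":
        return ColonyPlate(
            plate_id=self.plate_id,
            repeat_id=self.repeat_id,
            query_id=self.query_id,
            grid=grid,
            gene_map=self.gene_map,
        )


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chromosome: str
    position_bp: int


@dataclass
class GISResult:
    gene_id: str
    gis_per_repeat: dict[str, Optional[float]] = field(default_factory=dict)
    consensus_call: str = "none"  # negative | positive | none
    n_supporting_repeats: int = 0
    ambiguous: bool = False


def filter_colonies(
    control_plates: Sequence[ColonyPlate],
    min_size_px: float = SMALL_COLONY_PX,
) -> tuple[np.ndarray, list[ColonyPlate]]:
    """Mask positions whose control colony is absent or small.

    A position is excluded screen-wide if, on ANY control plate, the colony
    is absent (NaN) or below ``min_size_px``. Returns the boolean exclusion
    mask (True = excluded) and the control plates with those positions set
    to NaN. Apply the same mask to the query plates with
    :func:`apply_exclusion_mask`.
    """
    if not control_plates:
        raise InvalidInputError("control plates required")
    shape = control_plates[0].grid.shape
    mask = np.zeros(shape, dtype=bool)
    for plate in control_plates:
        if plate.grid.shape != shape:
            raise InvalidInputError("control plates have differing grid shapes")
        mask |= np.isnan(plate.grid) | (plate.grid < min_size_px)
    # positions with no gene are not part of the screen either way
    if mask.all():
        raise EmptyScreenError("every position excluded by control filtering")
    filtered = [apply_exclusion_mask(p, mask) for p in control_plates]
    return mask, filtered


def apply_exclusion_mask(plate: ColonyPlate, mask: np.ndarray) -> ColonyPlate:
    grid = plate.grid.copy()
    grid[mask] = np.nan
    return plate.copy_with(grid)


def _moving_median_surface(grid: np.ndarray, window: int) -> np.ndarray:
    """NaN-ignoring 2D moving median with reflect padding."""
    half = window // 2
    padded = np.pad(grid, half, mode="reflect")
    view = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        return np.nanmedian(view, axis=(2, 3))


def spatial_normalize(plate: ColonyPlate, window: int = 7) -> ColonyPlate:
    """Remove smooth spatial gradients and row/column effects.

    Two stages: (1) divide by a ``window x window`` moving-median surface
    (reflect-padded, excluded positions ignored) and rescale to the plate
    median; (2) divide each entry by its row-median/plate-median and
    column-median/plate-median factors. Excluded (NaN) positions stay
    excluded.
    """
    if window % 2 == 0 or window < 3:
        raise InvalidParameterError("window must be an odd integer >= 3")
    if window > min(plate.grid.shape):
        raise InvalidParameterError(
            f"window {window} exceeds grid dimensions {plate.grid.shape}"
        )
    grid = plate.grid
    finite = np.isfinite(grid)
    if finite.mean() < 0.5:
        raise InvalidInputError(">=50% of positions must be non-excluded")

    plate_median = np.nanmedian(grid)
    surface = _moving_median_surface(grid, window)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = grid / surface * plate_median

    grid_median = np.nanmedian(norm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_med = np.nanmedian(norm, axis=1, keepdims=True)
        col_med = np.nanmedian(norm, axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = norm / (row_med / grid_median) / (col_med / grid_median)
    # pin the plate median so normalization never rescales the whole plate
    norm = norm * (plate_median / np.nanmedian(norm))
    norm[~finite] = np.nan
    return plate.copy_with(norm)


def exclude_linked(
    annotations: Mapping[str, GeneAnnotation],
    loci: Iterable[str],
    scored_genes: Optional[Iterable[str]] = None,
    radius_bp: int = LINKAGE_RADIUS_BP,
) -> set[str]:
    """Genes within ``radius_bp`` (inclusive) of any marker locus, on the
    same chromosome, are flagged for exclusion as linked loci.

    Scored genes lacking an annotation trigger a warning but are retained.
    """
    locus_ann = []
    for locus in loci:
        if locus not in annotations:
            raise InvalidInputError(f"locus {locus!r} has no annotation")
        locus_ann.append(annotations[locus])

    genes = set(scored_genes) if scored_genes is not None else set(annotations)
    excluded: set[str] = set()
    for gene in genes:
        ann = annotations.get(gene)
        if ann is None:
            warnings.warn(
                f"gene {gene!r} has no annotation; retained in the screen",
                stacklevel=2,
            )
            continue
        for la in locus_ann:
            if ann.chromosome == la.chromosome and abs(
                ann.position_bp - la.position_bp
            ) <= radius_bp:
                excluded.add(gene)
                break
    return excluded


def _median_of(values: Sequence[float]) -> float:
    arr = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if arr.size == 0:
        return np.nan
    return float(np.median(arr))


def compute_gis(
    query_sizes: Mapping[str, Mapping[str, Sequence[float]]],
    control_sizes: Mapping[str, Mapping[str, Sequence[float]]],
    clip: float = GIS_CLIP,
) -> dict[str, GISResult]:
    """Per-repeat genetic interaction scores.

    Arguments map ``repeat_id -> gene_id -> normalised sizes``. The score is
    ``log10(median(query) / median(control))`` clipped to ``[-clip, +clip]``.
    A zero control median yields ``+clip`` when the query median is positive
    and an absent score otherwise; a gene absent from either arm of a repeat
    has no score for that repeat.
    """
    repeats = sorted(set(query_sizes) & set(control_sizes))
    if not repeats:
        raise InvalidInputError("no repeat present in both query and control")
    results: dict[str, GISResult] = {}
    for rep in repeats:
        q_map, c_map = query_sizes[rep], control_sizes[rep]
        for gene in set(q_map) & set(c_map):
            q_med = _median_of(q_map[gene])
            c_med = _median_of(c_map[gene])
            if not (np.isfinite(q_med) and np.isfinite(c_med)):
                continue
            if c_med == 0:
                gis = clip if q_med > 0 else None
            elif q_med == 0:
                gis = -clip
            else:
                gis = float(np.clip(np.log10(q_med / c_med), -clip, clip))
            res = results.setdefault(gene, GISResult(gene_id=gene))
            res.gis_per_repeat[rep] = gis
    return results


def call_hits(
    results: Mapping[str, GISResult],
    cutoff: float = DEFAULT_CUTOFF,
    min_repeats: int = DEFAULT_MIN_REPEATS,
) -> dict[str, GISResult]:
    """Fill consensus calls: a gene is a hit when the same sign reaches
    ``|gis| >= cutoff`` in at least ``min_repeats`` repeats; conflicting
    signs both reaching the threshold are flagged ambiguous (call=none)."""
    for res in results.values():
        scores = [g for g in res.gis_per_repeat.values() if g is not None]
        n_neg = sum(1 for g in scores if g <= -cutoff)
        n_pos = sum(1 for g in scores if g >= cutoff)
        res.ambiguous = False
        if n_neg >= min_repeats and n_pos >= min_repeats:
            res.consensus_call = "none"
            res.n_supporting_repeats = 0
            res.ambiguous = True
        elif n_neg >= min_repeats:
            res.consensus_call = "negative"
            res.n_supporting_repeats = n_neg
        elif n_pos >= min_repeats:
            res.consensus_call = "positive"
            res.n_supporting_repeats = n_pos
        else:
            res.consensus_call = "none"
            res.n_supporting_repeats = 0
    return dict(results)


def _collect_sizes(
    plates: Sequence[ColonyPlate],
) -> dict[str, dict[str, list[float]]]:
    out: dict[str, dict[str, list[float]]] = {}
    for plate in plates:
        rep = out.setdefault(plate.repeat_id, {})
        rows, cols = plate.grid.shape
        for i in range(rows):
            for j in range(cols):
                gene = plate.gene_map[i, j]
                size = plate.grid[i, j]
                if gene is None or not np.isfinite(size):
                    continue
                rep.setdefault(gene, []).append(float(size))
    return out


def score_screen(
    query_plates: Sequence[ColonyPlate],
    control_plates: Sequence[ColonyPlate],
    annotations: Optional[Mapping[str, GeneAnnotation]] = None,
    loci: Optional[Iterable[str]] = None,
    window: int = 7,
    cutoff: float = DEFAULT_CUTOFF,
    min_repeats: int = DEFAULT_MIN_REPEATS,
) -> pd.DataFrame:
    """Full screen scoring: filter -> normalize -> (linkage-)exclude ->
    GIS -> consensus calls. Returns a per-gene table."""
    mask, controls = filter_colonies(control_plates)
    queries = [apply_exclusion_mask(p, mask) for p in query_plates]
    controls = [spatial_normalize(p, window) for p in controls]
    queries = [spatial_normalize(p, window) for p in queries]

    q_sizes = _collect_sizes(queries)
    c_sizes = _collect_sizes(controls)
    results = compute_gis(q_sizes, c_sizes)

    linked: set[str] = set()
    if annotations is not None and loci is not None:
        linked = exclude_linked(annotations, loci, scored_genes=results.keys())
        results = {g: r for g, r in results.items() if g not in linked}

    results = call_hits(results, cutoff=cutoff, min_repeats=min_repeats)
    repeats = sorted({rep for r in results.values() for rep in r.gis_per_repeat})
    rows = []
    for gene in sorted(results):
        res = results[gene]
        row = {"gene_id": gene}
        for rep in repeats:
            row[f"gis_{rep}"] = res.gis_per_repeat.get(rep)
        row["consensus_call"] = res.consensus_call
        row["n_supporting_repeats"] = res.n_supporting_repeats
        row["ambiguous"] = res.ambiguous
        rows.append(row)
    for gene in sorted(linked):
        rows.append(
            {
                "gene_id": gene,
                "consensus_call": "excluded_linked",
                "n_supporting_repeats": 0,
                "ambiguous": False,
            }
        )
    return pd.DataFrame(rows)
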