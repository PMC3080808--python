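"""Density-estimate reference model.

Each gene of the labelled reference matrix is turned into a family of kernel
density estimates, one per tissue, all evaluated on a shared per-gene grid of
equally spaced points running from 0 to the gene's maximum observed value plus
twice its largest per-tissue bandwidth.  Bandwidths follow the normal-reference
rule of Scott (R's ``bw.nrd``), kernels are Gaussian, and the density is
computed by binned FFT convolution for speed.  Every density is renormalized
to unit area on its grid, so downstream scores can treat it as a probability
density restricted to the observed expression range.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import scipy.signal

from .config import Config
from .data import ExpressionMatrix
from .exceptions import (
    ConfigurationError,
    DegenerateDistributionError,
    InsufficientDataError,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# bandwidth


def scott_bandwidth(values: np.ndarray) -> float:
    """Normal-reference bandwidth 1.06 * min(sd, IQR/1.34) * n^(-1/5).

    Matches R's ``bw.nrd``: the spread estimate is the smaller of the sample
    standard deviation (ddof=1) and the interquartile range divided by 1.34;
    when the IQR is zero (heavily tied but not constant data) the sd alone is
    used so the gene remains usable.

    Raises
    ------
    InsufficientDataError
        fewer than 2 finite values.
    DegenerateDistributionError
        all values identical (no positive spread exists).
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = values.size
    if n < 2:
        raise InsufficientDataError(f"need >=2 observations, got {n}")
    sd = float(np.std(values, ddof=1))
    if sd == 0.0:
        raise DegenerateDistributionError("all observations identical")
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 1.06 * spread * n ** (-0.2)


# ---------------------------------------------------------------------------
# density estimation


def make_grid(gene_max: float, max_bandwidth: float, size: int = 512) -> np.ndarray:
    """Equally spaced evaluation points from 0 to gene_max + 2*max_bandwidth."""
    return np.linspace(0.0, gene_max + 2.0 * max_bandwidth, size)


def fit_density(
    values: np.ndarray, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Gaussian KDE evaluated on ``grid`` via binned FFT convolution.

    The data are linearly binned onto an internally refined copy of the grid
    (bin width at most bandwidth/512, so the binning error stays below 1e-6
    of the peak height) and convolved with a Gaussian kernel sampled at the
    same spacing.  The result is clamped at zero and renormalized to unit
    trapezoidal area over the grid.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise InsufficientDataError("no observations to estimate a density from")
    if not bandwidth > 0:
        raise ValueError("bandwidth must be positive")
    grid = np.asarray(grid, dtype=float)
    m = grid.size
    lo, hi = float(grid[0]), float(grid[-1])
    delta = (hi - lo) / (m - 1)

    refine = int(np.clip(np.ceil(512.0 * delta / bandwidth), 1, 4096))
    nf = (m - 1) * refine + 1
    step = (hi - lo) / (nf - 1)

    # linear binning of the observations onto the fine grid
    pos = np.clip((values - lo) / step, 0.0, nf - 1.0)
    i0 = np.floor(pos).astype(np.intp)
    i0 = np.minimum(i0, nf - 2)
    frac = pos - i0
    weights = np.zeros(nf)
    np.add.at(weights, i0, 1.0 - frac)
    np.add.at(weights, i0 + 1, frac)

    # Gaussian kernel truncated at 8 bandwidths (tail mass < 1e-15)
    half = min(nf - 1, int(np.ceil(8.0 * bandwidth / step)))
    x = np.arange(-half, half + 1) * step
    kernel = np.exp(-0.5 * (x / bandwidth) ** 2)

    dens = scipy.signal.fftconvolve(weights, kernel, mode="same")[::refine]
    dens = np.maximum(dens, 0.0)
    area = np.trapezoid(dens, grid)
    if not area > 0:
        raise InsufficientDataError("density has zero mass on the grid")
    return dens / area


def density_at(grid: np.ndarray, density: np.ndarray, x: float) -> float:
    """Linear interpolation of a density curve; zero outside the grid."""
    return float(np.interp(x, grid, density, left=0.0, right=0.0))


def support_range(values: np.ndarray, bandwidth: float) -> tuple[float, float]:
    """Effective support of a tissue's density: observed extremes plus a
    two-bandwidth smoothing margin (floored at zero, mirroring the grid's own
    two-bandwidth headroom).  Values beyond it count as outside the tissue's
    observed expression range."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    lo = max(0.0, float(values.min()) - 2.0 * bandwidth)
    hi = float(values.max()) + 2.0 * bandwidth
    return lo, hi


def truncate_to_range(
    density: np.ndarray, grid: np.ndarray, lo: float, hi: float
) -> np.ndarray | None:
    """Restrict a density curve to the observed range [lo, hi] and renormalize.

    A tissue's density carries meaning only over the expression range actually
    observed there: a query outside that range is a non-match by definition,
    so the curve is zeroed outside [lo, hi] and rescaled to unit area.
    Returns None when the range is narrower than the grid resolution (the
    distribution is then effectively a spike the grid cannot represent).
    """
    density = np.asarray(density, dtype=float)
    out = np.where((grid >= lo) & (grid <= hi), density, 0.0)
    area = np.trapezoid(out, grid)
    if not area > 0:
        return None
    return out / area


# ---------------------------------------------------------------------------
# modality


def detect_modality(
    density: np.ndarray,
    grid: np.ndarray,
    area_threshold: float = 0.1,
    min_prominence: float = 0.1,
) -> tuple[int, list[float]]:
    """Count density peaks carrying at least ``area_threshold`` of total area.

    The curve is segmented valley-to-valley around each local maximum
    (plateaus count once; boundary maxima count) and each segment's
    trapezoidal area is computed.  Returns the number of segments whose area
    reaches the threshold and the list of all segment areas.  A flat or
    monotone curve yields a single peak by convention.

    Local maxima whose prominence falls below ``min_prominence`` times the
    curve maximum are not treated as separate modes: finite-sample kernel
    estimates routinely carry shallow wiggles that would otherwise split one
    mode's area in two.
    """
    density = np.asarray(density, dtype=float)
    padded = np.concatenate(([-np.inf], density, [-np.inf]))
    peaks, _ = scipy.signal.find_peaks(
        padded, plateau_size=1, prominence=min_prominence * float(density.max())
    )
    peaks = peaks - 1  # undo padding offset
    if peaks.size == 0:
        return 1, [float(np.trapezoid(density, grid))]
    # valleys: minimum between consecutive peaks; outer boundaries close the ends
    bounds = [0]
    for left, right in zip(peaks[:-1], peaks[1:]):
        bounds.append(int(left + np.argmin(density[left : right + 1])))
    bounds.append(density.size - 1)
    areas = [
        float(np.trapezoid(density[a : b + 1], grid[a : b + 1]))
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    count = sum(1 for a in areas if a >= area_threshold)
    return count, areas


# ---------------------------------------------------------------------------
# the model


@dataclasses.dataclass
class GeneDensity:
    """Shared grid and per-tissue density estimates for one gene."""

    gene_id: str
    grid: np.ndarray  # (grid_size,) equally spaced, grid[0] == 0
    densities: dict[str, np.ndarray]  # tissue -> (grid_size,) unit-area curve
    bandwidths: dict[str, float]  # tissue -> bandwidth used
    gene_max: float  # max observed value across the whole reference
    ranges: dict[str, tuple[float, float]]  # tissue -> observed (min, max)

    def tissues(self) -> list[str]:
        return list(self.densities)


@dataclasses.dataclass
class ReferenceModel:
    genes: dict[str, GeneDensity]
    tissues: list[str]  # retained tissues, in label-sorted order
    tissue_counts: dict[str, int]
    excluded_genes: dict[str, str]  # gene id -> exclusion reason
    config: Config

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)


def _fit_gene(
    values_by_tissue: dict[str, np.ndarray], config: Config
) -> GeneDensity | str:
    """Fit one gene's grid and per-tissue densities.

    Returns a GeneDensity, or an exclusion-reason string when no tissue
    provides a usable (>=2 observations, non-degenerate) distribution.
    """
    bandwidths: dict[str, float] = {}
    for tissue, vals in values_by_tissue.items():
        if vals.size < 2:
            continue
        try:
            bandwidths[tissue] = scott_bandwidth(vals)
        except DegenerateDistributionError:
            continue  # density for this (gene, tissue) stays missing
    if not bandwidths:
        return "no tissue with >=2 non-missing, non-constant observations"
    gene_max = max(float(v.max()) for v in values_by_tissue.values() if v.size)
    grid = make_grid(gene_max, max(bandwidths.values()), config.grid_size)
    densities, ranges = {}, {}
    for t in list(bandwidths):
        vals = values_by_tissue[t]
        lo, hi = support_range(vals, bandwidths[t])
        curve = truncate_to_range(fit_density(vals, grid, bandwidths[t]), grid, lo, hi)
        if curve is None:  # range narrower than the grid can resolve
            del bandwidths[t]
            continue
        densities[t] = curve
        ranges[t] = (lo, hi)
    if not densities:
        return "no tissue distribution resolvable on the grid"
    return GeneDensity("", grid, densities, bandwidths, gene_max, ranges)


def _is_ambiguous(gene: GeneDensity, config: Config) -> bool:
    """Near-threshold modality: any peak with area in [threshold/2, threshold)."""
    lo = config.peak_area_threshold / 2.0
    hi = config.peak_area_threshold
    for dens in gene.densities.values():
        _, areas = detect_modality(dens, gene.grid, hi)
        if any(lo <= a < hi for a in areas):
            return True
    return False


def build_reference(matrix: ExpressionMatrix, config: Config = Config()) -> ReferenceModel:
    """Build the density reference from a labelled expression matrix.

    Tissues with fewer than ``config.min_tissue_size`` samples are dropped
    with a warning.  Genes lacking two non-missing observations in every
    retained tissue are excluded; optionally genes whose density shows a
    near-threshold ("ambiguous") peak are excluded as well.  The result is a
    pure function of (matrix, config).
    """
    counts = matrix.tissue_counts()
    kept = sorted(t for t, n in counts.items() if n >= config.min_tissue_size)
    dropped = sorted(set(counts) - set(kept))
    for t in dropped:
        log.warning(
            "dropping tissue %r: %d sample(s) < min_tissue_size=%d",
            t, counts[t], config.min_tissue_size,
        )
    if not kept:
        raise ConfigurationError(
            f"no tissue has >= {config.min_tissue_size} samples"
        )

    sample_groups = {t: matrix.samples_of(t) for t in kept}
    genes: dict[str, GeneDensity] = {}
    excluded: dict[str, str] = {}
    for gene_id in matrix.gene_ids:
        row = matrix.values.loc[gene_id]
        values_by_tissue = {
            t: row[cols].dropna().to_numpy(dtype=float)
            for t, cols in sample_groups.items()
        }
        fitted = _fit_gene(values_by_tissue, config)
        if isinstance(fitted, str):
            excluded[gene_id] = fitted
            continue
        fitted.gene_id = gene_id
        if config.ambiguous_modality_filter and _is_ambiguous(fitted, config):
            excluded[gene_id] = "ambiguous modality"
            continue
        genes[gene_id] = fitted

    if excluded:
        log.info("excluded %d/%d genes", len(excluded), len(matrix.gene_ids))
    return ReferenceModel(
        genes=genes,
        tissues=kept,
        tissue_counts={t: counts[t] for t in kept},
        excluded_genes=excluded,
        config=config,
    )
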