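"""Scoring a query profile against the density reference.

The tissue match score (tm-score) of a gene against a tissue is the fraction
of the gene's evaluation grid at which the tissue's density is no higher than
the density at the query's expression value; it is 1 when the query sits at
the tissue's most typical level and 0 when it falls outside the observed
range.  Comparing a gene's tm-score in one tissue with its tm-scores in all
other tissues via a ratio-weighted difference yields the tissue specificity
score (ts-score) in [-1, 1], and the mean ts-score over genes ranks candidate
tissues of origin.  Typicality calls flag query genes falling outside a
tissue's (1 - alpha) highest-density region.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import Config
from .data import clean_query
from .exceptions import ConfigurationError, DomainError, InputError
from .reference import GeneDensity, ReferenceModel, density_at

TYPICAL, ATYPICAL, UNDEFINED = "typical", "atypical", "undefined"


# ---------------------------------------------------------------------------
# tm-score


def tm_score(value: float, gene: GeneDensity, tissue: str) -> float:
    """Tissue match score of one expression value against one tissue density.

    Let d be the (linearly interpolated) density at the query value.  The
    score is |{i : f(grid_i) <= d}| / grid_size when d > 0 and 0 when d = 0,
    so a value at the unique global mode scores exactly 1 and a value outside
    the tissue's observed expression range scores 0 (the density has no
    support there).
    """
    dens = gene.densities[tissue]
    lo, hi = gene.ranges[tissue]
    if value < lo or value > hi:
        return 0.0
    d = density_at(gene.grid, dens, value)
    if d <= 0.0:
        return 0.0
    return float(np.count_nonzero(dens <= d)) / dens.size


def tm_profile(query: pd.Series, model: ReferenceModel) -> pd.DataFrame:
    """tm-scores for every query gene present in the model, in every tissue.

    Entries are NaN where the gene is absent from the query or the
    (gene, tissue) density is missing.  Raises if no query gene matches the
    model's gene universe.
    """
    query = clean_query(query)
    shared = [g for g in query.index if g in model.genes]
    if not shared:
        raise InputError("no query gene matches the reference model")
    tm = np.full((len(shared), len(model.tissues)), np.nan)
    tissue_idx = {t: j for j, t in enumerate(model.tissues)}
    for i, g in enumerate(shared):
        gene = model.genes[g]
        value = float(query[g])
        for t in gene.densities:
            tm[i, tissue_idx[t]] = tm_score(value, gene, t)
    return pd.DataFrame(tm, index=pd.Index(shared, name="gene"), columns=model.tissues)


# ---------------------------------------------------------------------------
# typicality


def typicality_null(gene: GeneDensity, tissue: str) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of tm-scores under the tissue's own density.

    Evaluates the tm-score at every grid point and weights it by the
    probability mass the density assigns to that point (trapezoidal weights,
    normalized to sum to 1).  Returns (tm_values, weights), both of grid
    length.
    """
    dens = gene.densities[tissue]
    m = dens.size
    step = gene.grid[1] - gene.grid[0]
    quad = np.full(m, step)
    quad[0] = quad[-1] = step / 2.0
    weights = dens * quad
    weights = weights / weights.sum()
    # tm at grid point i: fraction of grid with density <= dens[i] (0 if dens[i]=0)
    sorted_d = np.sort(dens)
    ranks = np.searchsorted(sorted_d, dens, side="right") / m
    ranks[dens <= 0.0] = 0.0
    return ranks, weights


def sample_from_density(
    gene: GeneDensity, tissue: str, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw values from the piecewise-linear density of one (gene, tissue).

    A grid cell is chosen proportional to its trapezoidal mass, then the
    position within the cell follows the linear density by exact inverse-CDF.
    """
    dens = gene.densities[tissue]
    grid = gene.grid
    step = grid[1] - grid[0]
    cell_mass = 0.5 * (dens[:-1] + dens[1:])
    p = cell_mass / cell_mass.sum()
    cells = rng.choice(p.size, size=size, p=p)
    d0, d1 = dens[cells], dens[cells + 1]
    u = rng.random(size)
    tot = d0 + d1
    slope = d1 - d0
    # within-cell CDF: (d0*t + slope*t^2/2) / (tot/2) = u
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(
            np.abs(slope) > 1e-12 * tot,
            (-d0 + np.sqrt(d0 * d0 + slope * u * tot)) / slope,
            u,
        )
    return grid[cells] + np.clip(t, 0.0, 1.0) * step


def null_cdf(gene: GeneDensity, tissue: str) -> tuple[np.ndarray, np.ndarray]:
    """Sorted tm atoms and cumulative mass of the typicality null."""
    tm_vals, weights = typicality_null(gene, tissue)
    order = np.argsort(tm_vals, kind="stable")
    tm_sorted = tm_vals[order]
    cum = np.cumsum(weights[order])
    return tm_sorted, cum


def call_typicality(
    tm: float, null: tuple[np.ndarray, np.ndarray], alpha: float = 0.05
) -> str:
    """Typical/atypical call: atypical iff P(TM <= tm) < alpha under the null.

    Equivalently, the query value lies outside the tissue's (1 - alpha)
    highest-density region.  tm-scores are exact multiples of 1/grid_size on
    both sides, so the <= comparison is exact.
    """
    if np.isnan(tm):
        return UNDEFINED
    tm_vals, weights = null
    p = float(weights[tm_vals <= tm].sum())
    return ATYPICAL if p < alpha else TYPICAL


# ---------------------------------------------------------------------------
# ts-score


def ratio_weighted_difference(a: float, b: float, phi: float = 0.25) -> float:
    """Ratio-weighted difference of two tm-scores, in [-1, 1].

    rwd(a, b) = (a - b) * (1 + phi) / (max(a, b) + phi).  Antisymmetric; for a
    fixed difference the magnitude grows as the larger score shrinks, so low
    tm pairs differentiate tissues more strongly than high ones.  At
    phi = 0.25 the pairs (0.5, 0) and (1, 0.5) score 5/6 and 1/2.
    """
    if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
        raise DomainError(f"tm-scores must lie in [0, 1], got ({a}, {b})")
    if not phi > 0:
        raise DomainError("phi must be positive")
    return (a - b) * (1.0 + phi) / (max(a, b) + phi)


def _rwd_pairwise(v: np.ndarray, phi: float) -> np.ndarray:
    """rwd(v_i, v_j) for all pairs of one gene's tm-scores (NaN-propagating)."""
    a = v[:, None]
    b = v[None, :]
    return (a - b) * (1.0 + phi) / (np.maximum(a, b) + phi)


def ts_matrix(tm: pd.DataFrame, phi: float = 0.25) -> pd.DataFrame:
    """Tissue specificity scores: per gene, mean rwd against all other tissues.

    ts(g, t) is the mean of rwd(tm(g, t), tm(g, o)) over every other tissue o
    with a non-missing tm-score; NaN where tm(g, t) is missing or no
    comparator tissue exists.
    """
    if tm.shape[1] < 2:
        raise ConfigurationError("ts-scores require at least 2 tissues")
    values = tm.to_numpy(dtype=float)
    out = np.full_like(values, np.nan)
    for i, v in enumerate(values):
        present = ~np.isnan(v)
        if present.sum() < 2:
            continue
        sub = v[present]
        pair = _rwd_pairwise(sub, phi)
        np.fill_diagonal(pair, 0.0)
        out_row = pair.sum(axis=1) / (present.sum() - 1)
        out[i, present] = out_row
    return pd.DataFrame(out, index=tm.index, columns=tm.columns)


# ---------------------------------------------------------------------------
# alignment


@dataclasses.dataclass
class AlignmentResult:
    """Full scoring of one query profile against a reference model."""

    tm: pd.DataFrame  # genes x tissues, [0, 1] or NaN
    ts: pd.DataFrame  # genes x tissues, [-1, 1] or NaN
    typicality: pd.DataFrame  # genes x tissues, typical/atypical/undefined
    similarity: pd.Series  # tissue -> mean non-missing ts
    coverage: pd.Series  # tissue -> number of genes informing similarity
    specific_counts: pd.Series  # tissue -> genes with ts > threshold
    ranking: list[str]  # tissues by descending similarity, ties lexicographic

    @property
    def top_tissue(self) -> str:
        return self.ranking[0]

    def scatter(self, tissue: str | None = None) -> pd.DataFrame:
        """Per-gene (tm, ts) table for one tissue (default: the top match)."""
        tissue = tissue or self.top_tissue
        return pd.DataFrame(
            {"tm": self.tm[tissue], "ts": self.ts[tissue]}
        ).dropna(how="all")


def rank_tissues(similarity: pd.Series) -> list[str]:
    """Descending similarity, ties broken by lexicographic tissue label."""
    return sorted(similarity.index, key=lambda t: (-similarity[t], t))


def align(
    query: pd.Series, model: ReferenceModel, config: Config | None = None
) -> AlignmentResult:
    """Score one query profile: tm/ts matrices, typicality, ranked tissues."""
    config = config or model.config
    if len(model.tissues) < 2:
        raise ConfigurationError("alignment requires a model with >=2 tissues")
    tm = tm_profile(query, model)
    ts = ts_matrix(tm, config.phi)

    calls = pd.DataFrame(UNDEFINED, index=tm.index, columns=tm.columns)
    for g in tm.index:
        gene = model.genes[g]
        for t in gene.densities:
            score = tm.at[g, t]
            if np.isnan(score):
                continue
            calls.at[g, t] = call_typicality(
                score, typicality_null(gene, t), config.alpha
            )

    similarity = ts.mean(axis=0, skipna=True)
    coverage = ts.notna().sum(axis=0)
    specific = (ts > config.ts_threshold).sum(axis=0)
    return AlignmentResult(
        tm=tm,
        ts=ts,
        typicality=calls,
        similarity=similarity,
        coverage=coverage,
        specific_counts=specific,
        ranking=rank_tissues(similarity),
    )
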