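"""Synthetic reference databases and query profiles with known ground truth.

The generator emulates the statistical structure of a curated bulk-expression
reference: per gene and tissue, expression follows a mixture of one to three
zero-truncated Gaussian components on a non-negative scale; a designated set
of marker genes is shifted upward in exactly one tissue by a fixed number of
within-tissue standard deviations; a fraction of genes is bimodal in one
tissue; measurements are missing at random.  Everything is a deterministic
function of the spec and its seed, and the true mixture parameters and marker
assignments are returned so recovery can be tested.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import ExpressionMatrix
from .exceptions import ConfigurationError

#: (weight, mean, sd) triples; weights sum to 1
Mixture = list[tuple[float, float, float]]


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Generative description of a synthetic reference database.

    Defaults are the shipped benchmark: 5 well-separated tissues with 20
    samples each, 100 genes of which 20 per tissue are markers shifted by 6
    within-tissue SDs, 16% of genes bimodal in one tissue, and 10% of
    measurements missing at random.
    """

    n_tissues: int = 5
    n_genes: int = 100
    samples_per_tissue: int = 20
    markers_per_tissue: int = 20
    marker_effect_sd: float = 6.0
    multimodal_fraction: float = 0.16
    missing_rate: float = 0.10
    seed: int = 0
    # base-expression ranges: means uniform on [mean_lo, mean_hi], within-tissue
    # coefficient of variation uniform on [cv_lo, cv_hi]
    mean_lo: float = 100.0
    mean_hi: float = 1000.0
    cv_lo: float = 0.08
    cv_hi: float = 0.20

    def __post_init__(self) -> None:
        if self.samples_per_tissue < 6:
            raise ConfigurationError("samples_per_tissue must be >= 6")
        if self.markers_per_tissue * self.n_tissues > self.n_genes:
            raise ConfigurationError(
                "more marker genes requested than genes available"
            )
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if not 0 <= self.multimodal_fraction <= 1:
            raise ConfigurationError("multimodal_fraction must lie in [0, 1]")

    @property
    def tissue_names(self) -> list[str]:
        return [f"tissue_{i:02d}" for i in range(self.n_tissues)]

    @property
    def gene_names(self) -> list[str]:
        return [f"gene_{i:04d}" for i in range(self.n_genes)]


@dataclasses.dataclass
class GroundTruth:
    """True generative parameters behind a synthetic reference."""

    spec: SyntheticSpec
    mixtures: dict[tuple[str, str], Mixture]  # (gene, tissue) -> components
    markers: dict[str, list[str]]  # tissue -> marker gene ids
    multimodal: dict[str, str]  # gene -> tissue where it is bimodal

    def marker_tissue(self, gene: str) -> str | None:
        for tissue, genes in self.markers.items():
            if gene in genes:
                return tissue
        return None


def _materialize(spec: SyntheticSpec) -> GroundTruth:
    """Draw the per-(gene, tissue) mixture parameters implied by the spec."""
    rng = np.random.default_rng(spec.seed)
    genes, tissues = spec.gene_names, spec.tissue_names

    base_mean = rng.uniform(spec.mean_lo, spec.mean_hi, size=spec.n_genes)
    base_sd = base_mean * rng.uniform(spec.cv_lo, spec.cv_hi, size=spec.n_genes)

    markers = {
        t: genes[i * spec.markers_per_tissue : (i + 1) * spec.markers_per_tissue]
        for i, t in enumerate(tissues)
    }
    marker_of = {g: t for t, gs in markers.items() for g in gs}

    n_multi = int(round(spec.multimodal_fraction * spec.n_genes))
    multi_genes = list(rng.choice(genes, size=n_multi, replace=False)) if n_multi else []
    multimodal: dict[str, str] = {}
    for g in multi_genes:
        # a marker gene is bimodal in its own marker tissue, so the second
        # mode never collides with another gene's marker level elsewhere
        if g in marker_of:
            multimodal[g] = marker_of[g]
        else:
            multimodal[g] = tissues[rng.integers(len(tissues))]

    mixtures: dict[tuple[str, str], Mixture] = {}
    for i, g in enumerate(genes):
        mu, sd = float(base_mean[i]), float(base_sd[i])
        for t in tissues:
            mean = mu + spec.marker_effect_sd * sd if marker_of.get(g) == t else mu
            if multimodal.get(g) == t:
                # two well-separated components of equal weight, the second
                # shifted further up so both stay clear of other tissues
                comp_sd = sd / 2.0
                mixtures[(g, t)] = [
                    (0.5, mean, comp_sd),
                    (0.5, mean + 3.5 * sd, comp_sd),
                ]
            else:
                mixtures[(g, t)] = [(1.0, mean, sd)]
    return GroundTruth(spec=spec, mixtures=mixtures, markers=markers,
                       multimodal=multimodal)


def _draw(mixture: Mixture, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample from a zero-truncated Gaussian mixture (negatives redrawn)."""
    weights = np.array([w for w, _, _ in mixture])
    comp = rng.choice(len(mixture), size=size, p=weights / weights.sum())
    means = np.array([m for _, m, _ in mixture])[comp]
    sds = np.array([s for _, _, s in mixture])[comp]
    out = rng.normal(means, sds)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(means[bad], sds[bad])
        bad = out < 0
    return out


def generate_reference(
    spec: SyntheticSpec = SyntheticSpec(),
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a labelled synthetic reference matrix plus its ground truth."""
    truth = _materialize(spec)
    rng = np.random.default_rng(np.random.default_rng(spec.seed).integers(2**31))

    columns, labels = [], {}
    for t in spec.tissue_names:
        for j in range(spec.samples_per_tissue):
            sid = f"{t}_s{j:02d}"
            columns.append(sid)
            labels[sid] = t

    values = np.empty((spec.n_genes, len(columns)))
    for gi, g in enumerate(spec.gene_names):
        col = 0
        for t in spec.tissue_names:
            values[gi, col : col + spec.samples_per_tissue] = _draw(
                truth.mixtures[(g, t)], spec.samples_per_tissue, rng
            )
            col += spec.samples_per_tissue
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values[mask] = np.nan

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=spec.gene_names, columns=columns),
        pd.Series(labels, name="tissue"),
    )
    return matrix, truth


def shift_perturbation(
    truth: GroundTruth, tissue: str, genes: list[str], n_sd: float
) -> dict[str, Mixture]:
    """Perturbation shifting listed genes by ``n_sd`` within-tissue SDs."""
    out = {}
    for g in genes:
        mixture = truth.mixtures[(g, tissue)]
        out[g] = [(w, m + n_sd * s, s) for w, m, s in mixture]
    return out


def generate_query(
    truth: GroundTruth,
    tissue: str,
    perturbation: dict[str, Mixture] | None = None,
    seed: int | None = None,
) -> tuple[pd.Series, list[str]]:
    """One query profile drawn from a tissue's generative model.

    ``perturbation`` overrides the generative mixture for listed genes; the
    returned list records those genes (the ones expected to be called
    atypical for the true tissue).
    """
    spec = truth.spec
    if tissue not in spec.tissue_names:
        raise KeyError(tissue)
    perturbation = perturbation or {}
    unknown = set(perturbation) - set(spec.gene_names)
    if unknown:
        raise KeyError(f"perturbed genes not in spec: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    values = {}
    for g in spec.gene_names:
        mixture = perturbation.get(g, truth.mixtures[(g, tissue)])
        values[g] = float(_draw(mixture, 1, rng)[0])
    return pd.Series(values, name="query"), sorted(perturbation)


def benchmark_spec(seed: int = 0) -> SyntheticSpec:
    """The versioned benchmark spec used by the validation suite."""
    return SyntheticSpec(seed=seed)
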