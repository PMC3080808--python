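"""Leave-one-out cross-validation of a reference database against itself.

Each sample is withdrawn in turn, the density estimates of its own tissue are
recalculated without it, and the sample is aligned against the resulting
model; the top-ranked tissue is the prediction.  Because the per-gene grid
depends on the gene-wide maximum value and the largest per-tissue bandwidth,
the grid (and with it all of that gene's tissue densities) is recomputed
whenever the removed sample determined either quantity; otherwise only the
left-out tissue's curve changes.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .config import Config
from .data import ExpressionMatrix
from .exceptions import ConfigurationError, DegenerateDistributionError
from .reference import (
    GeneDensity,
    ReferenceModel,
    build_reference,
    fit_density,
    make_grid,
    scott_bandwidth,
    support_range,
    truncate_to_range,
)
from .scoring import align

log = logging.getLogger(__name__)


@dataclasses.dataclass
class LoocvReport:
    records: pd.DataFrame  # sample, true, predicted, top/second tissue+similarity
    per_tissue: pd.DataFrame  # accuracy, sensitivity, specificity, n per tissue
    confusion: pd.DataFrame  # true x predicted counts (secondary-match view)
    overall_accuracy: float
    skipped: list[str]  # samples excluded from the denominator


def confusion_metrics(records: pd.DataFrame, tissue: str) -> tuple[float, float]:
    """Sensitivity tp/(tp+fn) and specificity tn/(tn+fp) for one tissue.

    tp: tissue samples predicted as the tissue; fn: tissue samples predicted
    elsewhere; fp: other samples predicted as the tissue; tn: the rest.
    """
    if records.empty:
        raise ValueError("no prediction records")
    if tissue not in set(records["true"]):
        raise KeyError(tissue)
    is_t = records["true"] == tissue
    pred_t = records["predicted"] == tissue
    tp = int((is_t & pred_t).sum())
    fn = int((is_t & ~pred_t).sum())
    fp = int((~is_t & pred_t).sum())
    tn = int((~is_t & ~pred_t).sum())
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    return sensitivity, specificity


def _loo_gene(
    gene: GeneDensity,
    values_by_tissue: dict[str, np.ndarray],
    tissue: str,
    config: Config,
) -> GeneDensity | None:
    """Refit one gene after removing a sample of ``tissue``.

    ``values_by_tissue`` holds the remaining per-tissue observations.
    Returns None when no usable tissue distribution remains.
    """
    vals_t = values_by_tissue.get(tissue, np.empty(0))
    bandwidths = dict(gene.bandwidths)
    bandwidths.pop(tissue, None)
    if vals_t.size >= 2:
        try:
            bandwidths[tissue] = scott_bandwidth(vals_t)
        except DegenerateDistributionError:
            pass
    if not bandwidths:
        return None

    def refit(t: str, grid: np.ndarray) -> np.ndarray | None:
        vals = values_by_tissue[t]
        curve = fit_density(vals, grid, bandwidths[t])
        return truncate_to_range(curve, grid, *support_range(vals, bandwidths[t]))

    gene_max = max(
        (float(v.max()) for v in values_by_tissue.values() if v.size),
        default=0.0,
    )
    upper = gene_max + 2.0 * max(bandwidths.values())
    if upper == gene.grid[-1]:
        # grid unchanged: only the left-out tissue's curve needs refitting
        densities = dict(gene.densities)
        ranges = dict(gene.ranges)
        densities.pop(tissue, None)
        ranges.pop(tissue, None)
        if tissue in bandwidths:
            curve = refit(tissue, gene.grid)
            if curve is None:
                del bandwidths[tissue]
            else:
                densities[tissue] = curve
                ranges[tissue] = support_range(vals_t, bandwidths[tissue])
        if not densities:
            return None
        return GeneDensity(gene.gene_id, gene.grid, densities, bandwidths,
                           gene_max, ranges)

    grid = make_grid(gene_max, max(bandwidths.values()), config.grid_size)
    densities, ranges = {}, {}
    for t in list(bandwidths):
        curve = refit(t, grid)
        if curve is None:
            del bandwidths[t]
            continue
        densities[t] = curve
        ranges[t] = support_range(values_by_tissue[t], bandwidths[t])
    if not densities:
        return None
    return GeneDensity(gene.gene_id, grid, densities, bandwidths, gene_max, ranges)


def loo_model(
    model: ReferenceModel, matrix: ExpressionMatrix, sample_id: str
) -> ReferenceModel:
    """The reference model rebuilt as if ``sample_id`` had never been seen."""
    tissue = matrix.tissue_labels[sample_id]
    remaining = [s for s in matrix.samples_of(tissue) if s != sample_id]
    sample_groups = {t: matrix.samples_of(t) for t in model.tissues}
    sample_groups[tissue] = remaining

    genes: dict[str, GeneDensity] = {}
    for gene_id, gene in model.genes.items():
        row = matrix.values.loc[gene_id]
        values_by_tissue = {
            t: row[cols].dropna().to_numpy(dtype=float)
            for t, cols in sample_groups.items()
        }
        refit = _loo_gene(gene, values_by_tissue, tissue, model.config)
        if refit is not None:
            genes[gene_id] = refit

    counts = dict(model.tissue_counts)
    counts[tissue] -= 1
    return ReferenceModel(
        genes=genes,
        tissues=model.tissues,
        tissue_counts=counts,
        excluded_genes=dict(model.excluded_genes),
        config=model.config,
    )


def loocv(matrix: ExpressionMatrix, config: Config = Config()) -> LoocvReport:
    """Leave-one-out cross-validation of the whole reference against itself.

    Samples of tissues that fall below the minimum tissue size (or would be
    reduced below min_tissue_size - 1 by their own removal) are skipped with
    a warning and excluded from the accuracy denominator.
    """
    model = build_reference(matrix, config)
    if len(model.tissues) < 2:
        raise ConfigurationError("LOOCV requires at least 2 retained tissues")

    rows = []
    skipped: list[str] = []
    for sample_id in matrix.sample_ids:
        tissue = matrix.tissue_labels[sample_id]
        if tissue not in model.tissue_counts:
            skipped.append(sample_id)
            continue
        if model.tissue_counts[tissue] - 1 < config.min_tissue_size - 1:
            log.warning("skipping %s: tissue %r would shrink below the size floor",
                        sample_id, tissue)
            skipped.append(sample_id)
            continue
        submodel = loo_model(model, matrix, sample_id)
        result = align(matrix.query_of(sample_id), submodel, config)
        top, second = result.ranking[0], result.ranking[1]
        rows.append(
            {
                "sample": sample_id,
                "true": tissue,
                "predicted": top,
                "similarity": result.similarity[top],
                "second": second,
                "second_similarity": result.similarity[second],
            }
        )

    records = pd.DataFrame(rows)
    if records.empty:
        raise ConfigurationError("no sample eligible for cross-validation")
    overall = float((records["true"] == records["predicted"]).mean())

    per_tissue_rows = {}
    for t in model.tissues:
        sub = records[records["true"] == t]
        if sub.empty:
            continue
        sens, spec = confusion_metrics(records, t)
        per_tissue_rows[t] = {
            "n": len(sub),
            "accuracy": float((sub["predicted"] == t).mean()),
            "sensitivity": sens,
            "specificity": spec,
        }
    per_tissue = pd.DataFrame.from_dict(per_tissue_rows, orient="index")
    per_tissue.index.name = "tissue"

    confusion = pd.crosstab(records["true"], records["predicted"]).reindex(
        index=model.tissues, columns=model.tissues, fill_value=0
    )
    return LoocvReport(
        records=records,
        per_tissue=per_tissue,
        confusion=confusion,
        overall_accuracy=overall,
        skipped=skipped,
    )
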