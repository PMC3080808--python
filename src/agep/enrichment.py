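"""Gene-set enrichment of atypical genes.

For a chosen reference tissue, genes called atypical form the "deviating part
of the transcriptome"; each gene set's relative enrichment among them is
fold = (k/m)/(M/N) for k set members atypical, M set members in the analyzed
background, m atypical genes and N background genes, with a one-sided
hypergeometric p-value P[X >= k].  A Benjamini-Hochberg q-value is reported
alongside the raw p-values.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.stats

from .scoring import ATYPICAL, TYPICAL

log = logging.getLogger(__name__)


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets; membership is intersected with an analyzed background."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def restricted(self, background: set[str]) -> "GeneSetCollection":
        """Intersect every set with the background, dropping empty results."""
        kept = {}
        for name, members in self.sets.items():
            inter = members & background
            if inter:
                kept[name] = inter
            else:
                log.warning("gene set %r is disjoint from the background; skipped",
                            name)
        return GeneSetCollection(kept, dict(self.descriptions))


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def enrich(typicality: pd.Series, sets: GeneSetCollection) -> pd.DataFrame:
    """Enrichment of each gene set among the atypically expressed genes.

    Parameters
    ----------
    typicality
        gene -> "typical"/"atypical" calls for one tissue; genes with other
        values (undefined) are excluded from the background.
    sets
        gene sets, intersected with the background before testing.

    Returns a DataFrame (set, k, M, m, N, fold, p, q) sorted by descending
    fold, ties broken by set name.
    """
    defined = typicality[typicality.isin([TYPICAL, ATYPICAL])]
    background = set(defined.index)
    atypical = set(defined.index[defined == ATYPICAL])
    N, m = len(background), len(atypical)
    columns = ["set", "k", "M", "m", "N", "fold", "p", "q"]
    if m == 0:
        log.warning("no atypical gene: enrichment is empty")
        return pd.DataFrame(columns=columns)

    usable = sets.restricted(background)
    rows = []
    for name in sorted(usable.sets):
        members = usable.sets[name]
        M = len(members)
        k = len(members & atypical)
        fold = (k * N) / (m * M)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, M, m))
        rows.append({"set": name, "k": k, "M": M, "m": m, "N": N,
                     "fold": fold, "p": p})
    if not rows:
        return pd.DataFrame(columns=columns)
    table = pd.DataFrame(rows)
    table["q"] = _bh_qvalues(table["p"].to_numpy())
    table = table.sort_values(["fold", "set"], ascending=[False, True])
    return table.reset_index(drop=True)
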