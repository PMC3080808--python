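"""Deterministic on-disk archive for reference models.

A model is stored as a single zip archive holding a JSON manifest (config,
tissue table, gene order, exclusions) and raw ``.npy`` arrays: the per-gene
grids, a genes x tissues x grid density cube (NaN slices where a density is
missing) and a genes x tissues bandwidth matrix.  Zip entries use a fixed
timestamp and sorted names, so saving the same model twice yields
byte-identical files, and floats round-trip exactly.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from pathlib import Path

import numpy as np

from .config import Config
from .reference import GeneDensity, ReferenceModel

_EPOCH = (1980, 1, 1, 0, 0, 0)
_FORMAT_VERSION = 1


def _npy_bytes(arr: np.ndarray) -> bytes:
    buf = _io.BytesIO()
    np.lib.format.write_array(buf, np.ascontiguousarray(arr), allow_pickle=False)
    return buf.getvalue()


def save_model(model: ReferenceModel, path: str | Path) -> None:
    genes = model.gene_ids
    tissues = model.tissues
    g, t, m = len(genes), len(tissues), model.config.grid_size

    grids = np.empty((g, m))
    dens = np.full((g, t, m), np.nan)
    bws = np.full((g, t), np.nan)
    ranges = np.full((g, t, 2), np.nan)
    gene_max = np.empty(g)
    for i, gid in enumerate(genes):
        entry = model.genes[gid]
        grids[i] = entry.grid
        gene_max[i] = entry.gene_max
        for j, tissue in enumerate(tissues):
            if tissue in entry.densities:
                dens[i, j] = entry.densities[tissue]
                bws[i, j] = entry.bandwidths[tissue]
                ranges[i, j] = entry.ranges[tissue]

    manifest = {
        "format_version": _FORMAT_VERSION,
        "config": model.config.to_dict(),
        "tissues": tissues,
        "tissue_counts": model.tissue_counts,
        "genes": genes,
        "excluded_genes": model.excluded_genes,
    }
    entries = {
        "manifest.json": json.dumps(manifest, sort_keys=True, indent=1).encode(),
        "arrays/grids.npy": _npy_bytes(grids),
        "arrays/densities.npy": _npy_bytes(dens),
        "arrays/bandwidths.npy": _npy_bytes(bws),
        "arrays/gene_max.npy": _npy_bytes(gene_max),
        "arrays/ranges.npy": _npy_bytes(ranges),
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(entries):
            info = zipfile.ZipInfo(name, date_time=_EPOCH)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zf.writestr(info, entries[name])


def load_model(path: str | Path) -> ReferenceModel:
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        grids = np.lib.format.read_array(_io.BytesIO(zf.read("arrays/grids.npy")))
        dens = np.lib.format.read_array(_io.BytesIO(zf.read("arrays/densities.npy")))
        bws = np.lib.format.read_array(_io.BytesIO(zf.read("arrays/bandwidths.npy")))
        gene_max = np.lib.format.read_array(
            _io.BytesIO(zf.read("arrays/gene_max.npy"))
        )
        ranges = np.lib.format.read_array(_io.BytesIO(zf.read("arrays/ranges.npy")))
    tissues = manifest["tissues"]
    genes: dict[str, GeneDensity] = {}
    for i, gid in enumerate(manifest["genes"]):
        densities, bandwidths, obs_ranges = {}, {}, {}
        for j, tissue in enumerate(tissues):
            if np.isfinite(bws[i, j]):
                densities[tissue] = dens[i, j].copy()
                bandwidths[tissue] = float(bws[i, j])
                obs_ranges[tissue] = (float(ranges[i, j, 0]), float(ranges[i, j, 1]))
        genes[gid] = GeneDensity(
            gene_id=gid,
            grid=grids[i].copy(),
            densities=densities,
            bandwidths=bandwidths,
            gene_max=float(gene_max[i]),
            ranges=obs_ranges,
        )
    return ReferenceModel(
        genes=genes,
        tissues=tissues,
        tissue_counts={k: int(v) for k, v in manifest["tissue_counts"].items()},
        excluded_genes=dict(manifest["excluded_genes"]),
        config=Config.from_dict(manifest["config"]),
    )
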