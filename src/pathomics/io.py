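"""Readers and writers for the pipeline's on-disk formats.

Rasters go through imageio (PNG/TIFF); tabular artifacts are CSV/TSV via
pandas; gene sets use the GMT convention (set name, description, then
tab-separated gene ids, one set per line).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "read_image",
    "write_image",
    "read_gmt",
    "write_gmt",
    "write_patch_manifest",
    "write_density_sidecar",
    "read_labels_csv",
    "read_expression_tsv",
]


def read_image(path) -> np.ndarray:
    return iio.imread(path)


def write_image(path, image: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(image))


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: gene id list}."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(path, gene_sets: dict[str, list[str]],
              descriptions: dict[str, str] | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for name, genes in gene_sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_patch_manifest(path, records, slide_id: str | None = None) -> pd.DataFrame:
    """Write the per-patch manifest CSV (slide_id, x, y, coverage, accepted)."""
    rows = [dict(slide_id=r.slide_id or slide_id, x=r.x, y=r.y,
                 nuclei_coverage=r.nuclei_coverage, accepted=r.accepted)
            for r in records]
    df = pd.DataFrame(rows, columns=["slide_id", "x", "y",
                                     "nuclei_coverage", "accepted"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return df


def write_density_sidecar(path, dmap) -> None:
    """JSON sidecar of a density map: tile size and the raw counts grid."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    payload = dict(tile_px=int(dmap.tile_px),
                   counts=np.asarray(dmap.counts).tolist())
    Path(path).write_text(json.dumps(payload))


def read_labels_csv(path, id_column: str = "sample_id",
                    label_column: str = "label") -> pd.Series:
    df = pd.read_csv(path)
    return df.set_index(id_column)[label_column]


def read_expression_tsv(path) -> pd.DataFrame:
    """Gene × sample expression matrix, first column = gene ids."""
    return pd.read_csv(path, sep="\t", index_col=0)
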