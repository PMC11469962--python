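"""Readers and writers for the plain-text interchange formats.

Count matrices travel as Matrix Market coordinate files (genes as rows,
1-based indices) alongside TSV gene/cell lists and a TSV cell-metadata table.
Ortholog maps, somite measurement tables and intensity profiles are TSV;
fitted staging models and correspondence results are JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .containers import CellMatrix, FormatError, IntensityProfile, OrthologMap

logger = logging.getLogger(__name__)

__all__ = [
    "read_cell_matrix",
    "write_cell_matrix",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_somite_table",
    "write_somite_table",
    "read_intensity_profile",
    "write_intensity_profile",
    "read_staging_model",
    "write_staging_model",
]

SOMITE_COLUMNS = ["gastruloid_id", "side", "order_from_posterior", "area", "length", "width"]


def read_cell_matrix(matrix_path, genes_path, cells_path, meta_path) -> CellMatrix:
    """Load a CellMatrix from MTX + TSV files.

    ``genes_path`` and ``cells_path`` are single-column TSVs without header;
    ``meta_path`` is a TSV with a ``cell_id`` column joined onto the cell list.
    """
    for p in (matrix_path, genes_path, cells_path, meta_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    counts = sio.mmread(str(matrix_path))
    counts = sp.csr_matrix(counts)
    genes = pd.Index(
        pd.read_csv(genes_path, sep="\t", header=None, dtype=str).iloc[:, 0]
        if Path(genes_path).stat().st_size
        else [],
        name="gene_id",
    )
    cells = pd.Index(
        pd.read_csv(cells_path, sep="\t", header=None, dtype=str).iloc[:, 0]
        if Path(cells_path).stat().st_size
        else [],
        name="cell_id",
    )
    meta = pd.read_csv(meta_path, sep="\t", dtype={"cell_id": str})
    if "cell_id" not in meta.columns:
        raise FormatError(f"{meta_path}: metadata requires a 'cell_id' column")
    meta = meta.set_index("cell_id")
    missing = cells.difference(meta.index)
    if len(missing):
        raise FormatError(f"metadata missing cell ids: {missing.tolist()[:5]}")
    meta = meta.loc[cells]
    if counts.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix shape {counts.shape} does not match gene/cell lists "
            f"({len(genes)}, {len(cells)})"
        )
    return CellMatrix(counts, genes, meta)


def write_cell_matrix(cm: CellMatrix, matrix_path, genes_path, cells_path, meta_path) -> None:
    coo = cm.counts.tocoo()
    # integer field keeps round-trips bit-exact
    sio.mmwrite(str(matrix_path), sp.coo_matrix(
        (coo.data.astype(np.int64), (coo.row, coo.col)), shape=coo.shape
    ), field="integer")
    pd.Series(cm.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)
    pd.Series(cm.cell_ids).to_csv(cells_path, sep="\t", header=False, index=False)
    cm.cell_meta.rename_axis("cell_id").reset_index().to_csv(meta_path, sep="\t", index=False)


def read_ortholog_map(path) -> OrthologMap:
    """Read a two-column TSV (with header) of ortholog pairs.

    Exact duplicate rows are collapsed with a logged warning; many-to-many
    relationships are retained.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: ortholog map needs at least two columns")
    om = OrthologMap(table)
    if om.n_duplicates_dropped:
        logger.warning("%s: collapsed %d duplicate ortholog pairs", path, om.n_duplicates_dropped)
    return om


def write_ortholog_map(om: OrthologMap, path) -> None:
    om.pairs.to_csv(path, sep="\t", index=False)


def read_somite_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in SOMITE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: somite table missing columns {missing}")
    if (table[["area", "length", "width"]] <= 0).any().any():
        raise FormatError(f"{path}: somite measurements must be positive")
    if table.duplicated(["gastruloid_id", "side", "order_from_posterior"]).any():
        raise FormatError(f"{path}: duplicate (gastruloid, side, order) rows")
    return table


def write_somite_table(table: pd.DataFrame, path) -> None:
    table[SOMITE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_intensity_profile(path) -> IntensityProfile:
    table = pd.read_csv(path, sep="\t")
    if "position" not in table.columns:
        raise FormatError(f"{path}: intensity profile requires a 'position' column")
    return IntensityProfile(
        table["position"].to_numpy(), table.drop(columns="position")
    )


def write_intensity_profile(profile: IntensityProfile, path) -> None:
    out = profile.intensity.copy()
    out.insert(0, "position", profile.positions)
    out.to_csv(path, sep="\t", index=False)


def write_staging_model(model, path) -> None:
    """Serialize a StagingModel to JSON (loadings at full float precision)."""
    path = Path(path)
    path.write_text(json.dumps(model.to_dict(), indent=1))


def read_staging_model(path):
    from .staging import StagingModel

    return StagingModel.from_dict(json.loads(Path(path).read_text()))
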