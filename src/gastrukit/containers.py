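"""In-memory containers shared across the pipeline.

The package operates on four kinds of tabular objects:

* :class:`CellMatrix` — a sparse gene x cell UMI count matrix with per-cell
  metadata (individual, cell type, stage, species, model).
* :class:`PseudobulkMatrix` — a dense gene x sample matrix obtained by
  aggregating a :class:`CellMatrix`, tracked through the normalization chain
  (``raw`` -> ``depth_normalized`` -> ``log`` -> ``z``).
* :class:`OrthologMap` — a many-to-many correspondence between the gene
  namespaces of two species.
* :class:`IntensityProfile` — 1-D fluorescence intensity tracks along a
  body axis, used by the somite-boundary analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CellMatrix",
    "PseudobulkMatrix",
    "OrthologMap",
    "IntensityProfile",
    "FormatError",
]

#: metadata columns a CellMatrix is expected to carry (extra columns pass through)
CELL_META_COLUMNS = (
    "individual_id",
    "cell_type",
    "stage_label",
    "stage_value",
    "species",
    "model",
)


class FormatError(ValueError):
    """Raised when an on-disk file or in-memory object violates the format contract."""


def _positions(keep) -> np.ndarray:
    """Boolean masks become positions; integer arrays are positions already."""
    arr = np.asarray(keep)
    return np.flatnonzero(arr) if arr.dtype == bool else arr.astype(int)


@dataclass
class CellMatrix:
    """Sparse gene x cell UMI counts plus per-cell metadata.

    ``counts`` has genes as rows and cells as columns; ``cell_meta`` is indexed
    by cell id, aligned with the columns of ``counts``.
    """

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    def validate(self) -> None:
        if self.counts.shape != (len(self.gene_ids), len(self.cell_meta)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_meta)} cells"
            )
        if self.gene_ids.has_duplicates:
            dups = self.gene_ids[self.gene_ids.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if self.cell_meta.index.has_duplicates:
            dups = self.cell_meta.index[self.cell_meta.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate cell ids: {dups[:5]}")
        data = self.counts.data
        if data.size:
            if (data < 0).any():
                raise FormatError("negative entries in count matrix")
            if not np.allclose(data, np.round(data)):
                bad = data[~np.isclose(data, np.round(data))][:5]
                raise FormatError(f"non-integer entries in count matrix: {bad}")

    def subset_genes(self, keep: np.ndarray | pd.Index) -> "CellMatrix":
        """Return a new CellMatrix restricted to ``keep`` (boolean mask or gene ids)."""
        if isinstance(keep, (pd.Index, list, tuple)):
            idx = self.gene_ids.get_indexer(pd.Index(keep))
            if (idx < 0).any():
                missing = pd.Index(keep)[idx < 0].tolist()
                raise KeyError(f"genes not present: {missing[:5]}")
        else:
            idx = _positions(keep)
        return CellMatrix(self.counts[idx], self.gene_ids[idx], self.cell_meta.copy())

    def subset_cells(self, keep: np.ndarray | pd.Index) -> "CellMatrix":
        if isinstance(keep, (pd.Index, list, tuple)):
            idx = self.cell_meta.index.get_indexer(pd.Index(keep))
            if (idx < 0).any():
                missing = pd.Index(keep)[idx < 0].tolist()
                raise KeyError(f"cells not present: {missing[:5]}")
        else:
            idx = _positions(keep)
        return CellMatrix(
            self.counts[:, idx], self.gene_ids, self.cell_meta.iloc[idx].copy()
        )


VALID_STAGES = ("raw", "depth_normalized", "log", "z")


@dataclass
class PseudobulkMatrix:
    """Dense gene x sample matrix with sample metadata.

    ``stage`` records where the matrix sits in the normalization chain.  A
    ``raw`` matrix holds integral UMI sums; a ``z`` matrix is per-gene
    centred/scaled across samples.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    stage: str = "raw"
    zero_variance_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in VALID_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {VALID_STAGES}")
        if not self.values.columns.equals(self.sample_meta.index):
            raise FormatError("pseudobulk columns and sample metadata index differ")
        if self.stage == "raw":
            arr = self.values.to_numpy()
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise FormatError("raw pseudobulk must hold non-negative integers")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class OrthologMap:
    """Gene correspondence between two species; many-to-many pairs allowed."""

    pairs: pd.DataFrame  # columns: gene_species1, gene_species2

    def __post_init__(self) -> None:
        cols = list(self.pairs.columns)
        if len(cols) < 2:
            raise FormatError("ortholog map needs two columns")
        self.pairs = self.pairs.iloc[:, :2].copy()
        self.pairs.columns = ["gene_species1", "gene_species2"]
        n_before = len(self.pairs)
        self.pairs = self.pairs.drop_duplicates(ignore_index=True)
        self.n_duplicates_dropped = n_before - len(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def mapping(self, direction: str) -> pd.DataFrame:
        """Return a two-column frame (source, target) for the given direction.

        ``direction`` is ``"to_species1"`` (species-2 genes relabelled into the
        species-1 namespace) or ``"to_species2"``.
        """
        if direction == "to_species1":
            return self.pairs.rename(
                columns={"gene_species2": "source", "gene_species1": "target"}
            )[["source", "target"]]
        if direction == "to_species2":
            return self.pairs.rename(
                columns={"gene_species1": "source", "gene_species2": "target"}
            )[["source", "target"]]
        raise ValueError("direction must be 'to_species1' or 'to_species2'")

    @staticmethod
    def identity(genes) -> "OrthologMap":
        genes = pd.Index(genes)
        return OrthologMap(pd.DataFrame({"gene_species1": genes, "gene_species2": genes}))


@dataclass
class IntensityProfile:
    """Per-position fluorescence intensities for one or more channels."""

    positions: np.ndarray
    intensity: pd.DataFrame  # one column per channel

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        if len(self.positions) != len(self.intensity):
            raise FormatError("positions and intensity have different lengths")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise FormatError("positions must be strictly increasing")
        if (self.intensity.to_numpy() < 0).any():
            raise FormatError("intensities must be non-negative")
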