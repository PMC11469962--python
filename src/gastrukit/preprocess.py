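"""QC filtering, pseudobulk aggregation and the pre-PCA normalization chain.

Single-cell QC here is rule-based: a gene-pattern filter against cell-cycle
and housekeeping families, a kernel-density valley finder for bimodal UMI
count distributions, and marker-based cell exclusion.  Pseudobulking sums
UMIs per sample (or per sample and cell type), and ``normalize_chain``
applies depth normalization -> log1p -> per-gene z-scoring, the state in
which pseudobulk profiles enter PCA staging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import gaussian_kde

from .containers import CellMatrix, PseudobulkMatrix

__all__ = [
    "DEFAULT_GENE_FILTER",
    "GeneFilterReport",
    "filter_genes_by_pattern",
    "find_bimodal_valley",
    "pseudobulk",
    "normalize_chain",
    "depth_normalize",
    "filter_cells_by_counts",
    "exclude_cells_by_marker",
]

# cell-cycle / housekeeping family token lists used for gene removal
DEFAULT_GENE_FILTER = {
    "prefixes": ("HIST", "MT", "TOP", "CDK", "CCN", "CDC", "CCDC", "MKI"),
    "substrings": ("MALAT", "AUR"),
    "suffixes": (
        "NUSAP", "SMC", "CENP", "UBE", "SGO", "ASPM", "PLK", "KPN", "RP",
        "PTTG", "SNHG", "CK", "BUB", "KIF", "KCNQ", "SMO", "HMG", "S100",
        "LINC", "ATP", "IGFBP", "HSP", "FOS", "JUN",
    ),
}


@dataclass
class GeneFilterReport:
    removed: pd.Index
    reasons: pd.Series  # per removed gene: which pattern matched


def filter_genes_by_pattern(
    cm: CellMatrix,
    prefixes=DEFAULT_GENE_FILTER["prefixes"],
    substrings=DEFAULT_GENE_FILTER["substrings"],
    suffixes=DEFAULT_GENE_FILTER["suffixes"],
) -> tuple[CellMatrix, GeneFilterReport]:
    """Drop genes whose (uppercased) id matches any family token.

    Prefix tokens match at the start of the id, substring tokens anywhere and
    suffix tokens at the end.  Returns the filtered matrix and a report of
    removed genes with the first matching pattern.
    """
    genes = cm.gene_ids.str.upper()
    reasons = {}
    for g, gu in zip(cm.gene_ids, genes):
        hit = None
        for tok in prefixes:
            if gu.startswith(tok):
                hit = f"prefix:{tok}"
                break
        if hit is None:
            for tok in substrings:
                if tok in gu:
                    hit = f"substring:{tok}"
                    break
        if hit is None:
            for tok in suffixes:
                if gu.endswith(tok):
                    hit = f"suffix:{tok}"
                    break
        if hit is not None:
            reasons[g] = hit
    removed = pd.Index(list(reasons), name="gene_id")
    keep = ~cm.gene_ids.isin(removed)
    if not keep.any():
        raise ValueError("gene-pattern filter removed every gene")
    report = GeneFilterReport(removed, pd.Series(reasons, dtype=object))
    return cm.subset_genes(np.asarray(keep)), report


def find_bimodal_valley(values, n_grid: int = 512, rel_prominence: float = 0.05):
    """Valley of a bimodal distribution of positive values, on a log10 scale.

    A Gaussian KDE of ``log10(values)`` is evaluated on a grid; the two
    highest local density maxima are located and the threshold returned is
    ``10 ** argmin`` of the density between them.  If the density is
    effectively unimodal (fewer than two modes of meaningful prominence, or
    merged modes), returns ``None`` and the caller must supply a manual
    threshold.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 50:
        raise ValueError("need at least 50 values for valley detection")
    if (values <= 0).any():
        raise ValueError("values must be strictly positive")
    logv = np.log10(values)
    if np.ptp(logv) < 1e-12:
        return None
    kde = gaussian_kde(logv)
    grid = np.linspace(logv.min(), logv.max(), n_grid)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1
    # discard shoulder modes far below the global peak
    peaks = [i for i in interior if dens[i] >= rel_prominence * dens.max()]
    if len(peaks) < 2:
        return None
    top2 = sorted(sorted(peaks, key=lambda i: dens[i], reverse=True)[:2])
    lo, hi = top2
    if hi - lo < 2:
        return None
    seg = slice(lo, hi + 1)
    valley = lo + int(np.argmin(dens[seg]))
    if dens[valley] >= min(dens[lo], dens[hi]) - 1e-12:
        return None  # no real dip between the modes
    return float(10 ** grid[valley])


def filter_cells_by_counts(
    cm: CellMatrix, min_umi: float | None = None, max_umi: float | None = None
) -> CellMatrix:
    """Keep cells whose total UMI count lies in [min_umi, max_umi]."""
    totals = np.asarray(cm.counts.sum(axis=0)).ravel()
    keep = np.ones(cm.n_cells, dtype=bool)
    if min_umi is not None:
        keep &= totals >= min_umi
    if max_umi is not None:
        keep &= totals <= max_umi
    if "doublet_flag" in cm.cell_meta.columns:
        keep &= ~cm.cell_meta["doublet_flag"].fillna(False).astype(bool).to_numpy()
    return cm.subset_cells(keep)


def exclude_cells_by_marker(cm: CellMatrix, markers, threshold: float = 1.0) -> CellMatrix:
    """Drop cells expressing any marker gene at >= threshold counts."""
    present = [g for g in markers if g in cm.gene_ids]
    if not present:
        return cm
    idx = cm.gene_ids.get_indexer(pd.Index(present))
    sub = cm.counts[idx].toarray()
    keep = ~(sub >= threshold).any(axis=0)
    return cm.subset_cells(keep)


def pseudobulk(cm: CellMatrix, group_by=("individual_id",)) -> PseudobulkMatrix:
    """Sum UMI counts per group of cells.

    ``group_by`` is a tuple of metadata columns, typically
    ``("individual_id",)`` for whole-sample staging or
    ``("individual_id", "cell_type")`` for lineage-specific staging.  Total
    counts are conserved: the grand total of the output equals the input's.
    """
    group_by = list(group_by)
    for col in group_by:
        if col not in cm.cell_meta.columns:
            raise KeyError(f"grouping column {col!r} not in cell metadata")
    keys = cm.cell_meta[group_by].astype(str).agg("|".join, axis=1)
    if keys.empty:
        raise ValueError("no cells to pseudobulk")
    uniq = pd.Index(sorted(keys.unique()))
    # indicator matrix: cells x groups
    col_idx = uniq.get_indexer(keys)
    ind = sp.csr_matrix(
        (np.ones(len(keys)), (np.arange(len(keys)), col_idx)),
        shape=(len(keys), len(uniq)),
    )
    summed = np.asarray((cm.counts @ ind).todense())
    values = pd.DataFrame(summed, index=cm.gene_ids, columns=uniq)

    meta_rows = []
    grouped = cm.cell_meta.groupby(keys.values, sort=True)
    for key, sub in grouped:
        row = {"n_cells_aggregated": len(sub)}
        for col in group_by:
            row[col] = sub[col].iloc[0]
        for col in sub.columns:  # carry metadata that is constant within the group
            if col not in row:
                vals = sub[col].dropna().unique()
                row[col] = vals[0] if len(vals) == 1 else np.nan
        meta_rows.append(pd.Series(row, name=key))
    sample_meta = pd.DataFrame(meta_rows).loc[uniq]
    return PseudobulkMatrix(values, sample_meta, stage="raw")


def depth_normalize(pb: PseudobulkMatrix, scale: float = 1e4) -> PseudobulkMatrix:
    """Counts per ``scale`` total: each column divided by its sum, times scale."""
    if pb.stage != "raw":
        raise ValueError(f"expected a raw matrix, got stage={pb.stage!r}")
    totals = pb.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total samples: {zero.index.tolist()[:5]}")
    values = pb.values / totals * scale
    return PseudobulkMatrix(values, pb.sample_meta.copy(), stage="depth_normalized")


def normalize_chain(pb: PseudobulkMatrix, scale: float = 1e4) -> PseudobulkMatrix:
    """Depth-normalize, log1p, then z-score each gene across samples.

    z-scoring uses the sample (n-1) standard deviation.  Genes with zero
    variance across samples are set to z = 0 and listed in
    ``zero_variance_genes``.
    """
    dn = depth_normalize(pb, scale=scale)
    logged = np.log1p(dn.values)
    means = logged.mean(axis=1)
    sds = logged.std(axis=1, ddof=1) if logged.shape[1] > 1 else pd.Series(0.0, index=logged.index)
    flat = sds <= 0
    safe = sds.where(~flat, 1.0)
    z = logged.sub(means, axis=0).div(safe, axis=0)
    z[flat] = 0.0
    out = PseudobulkMatrix(z, pb.sample_meta.copy(), stage="z")
    out.zero_variance_genes = z.index[flat].tolist()
    return out
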