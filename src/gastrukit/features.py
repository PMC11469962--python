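"""Feature selection and cross-species feature-space conversion.

Highly variable genes are called against a Poisson noise model: with
depth-adjusted expected counts ``mu_gs = (gene total) * (sample total) /
(grand total)``, the Pearson dispersion statistic ``sum_s (x_gs - mu_gs)^2 /
mu_gs`` is chi-square with S-1 degrees of freedom under Poisson sampling.
Genes exceeding it after Benjamini-Hochberg correction are selected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import OrthologMap, PseudobulkMatrix

logger = logging.getLogger(__name__)

__all__ = ["poisson_hvg", "convert_features", "intersect_features"]


def poisson_hvg(counts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Poisson-overdispersion test per gene on a raw gene x sample matrix.

    Returns a frame with ``dispersion_statistic``, ``p_value``, ``q_value``
    (BH) and ``selected`` per gene.  Genes with zero total counts are
    excluded from testing (``excluded=True``, no p-value).
    """
    if isinstance(counts, PseudobulkMatrix):
        if counts.stage != "raw":
            raise ValueError("poisson_hvg requires raw counts")
        counts = counts.values
    arr = counts.to_numpy(dtype=float)
    if arr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    gene_tot = arr.sum(axis=1)
    samp_tot = arr.sum(axis=0)
    grand = arr.sum()
    excluded = gene_tot == 0
    mu = np.outer(gene_tot, samp_tot) / grand
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(mu > 0, (arr - mu) ** 2 / np.where(mu > 0, mu, 1.0), 0.0).sum(axis=1)
    dof = arr.shape[1] - 1
    p = stats.chi2.sf(stat, dof)
    result = pd.DataFrame(
        {
            "dispersion_statistic": stat,
            "p_value": p,
            "q_value": np.nan,
            "selected": False,
            "excluded": excluded,
        },
        index=counts.index,
    )
    tested = ~excluded
    if tested.any():
        rej, q, *_ = multipletests(p[tested], alpha=alpha, method="fdr_bh")
        result.loc[tested, "q_value"] = q
        result.loc[tested, "selected"] = rej
    result.loc[excluded, ["dispersion_statistic", "p_value"]] = np.nan
    return result


def convert_features(
    pb: PseudobulkMatrix,
    omap: OrthologMap,
    direction: str,
    collision: str = "sum",
) -> PseudobulkMatrix:
    """Re-index a pseudobulk matrix into the other species' gene namespace.

    A source gene mapping to k targets contributes its full row to each
    target; multiple sources mapping to one target are summed (``collision=
    "sum"``, the additive choice for counts) or the first in gene-id order is
    kept (``collision="first"``).  Unmapped source genes are dropped with a
    logged count.  Conversion must precede z-scoring.
    """
    if pb.stage not in ("raw", "depth_normalized"):
        raise ValueError("convert_features requires a raw or depth_normalized matrix")
    if collision not in ("sum", "first"):
        raise ValueError("collision must be 'sum' or 'first'")
    pairs = omap.mapping(direction)
    pairs = pairs[pairs["source"].isin(pb.gene_ids)]
    if pairs.empty:
        raise ValueError("no overlap between matrix genes and ortholog map")
    n_unmapped = pb.values.shape[0] - pb.gene_ids.isin(pairs["source"]).sum()
    if n_unmapped:
        logger.info("convert_features: dropped %d unmapped genes", n_unmapped)
    expanded = pb.values.loc[pairs["source"]].set_axis(pairs["target"].to_numpy(), axis=0)
    if collision == "sum":
        converted = expanded.groupby(level=0, sort=True).sum()
    else:
        expanded = expanded.sort_index(kind="stable")
        converted = expanded[~expanded.index.duplicated(keep="first")]
    converted.index.name = "gene_id"
    return PseudobulkMatrix(converted, pb.sample_meta.copy(), stage=pb.stage)


def intersect_features(feature_sets) -> pd.Index:
    """Sorted intersection of >= 2 gene-id collections; errors when empty."""
    feature_sets = [set(s) for s in feature_sets]
    if len(feature_sets) < 2:
        raise ValueError("need at least two feature sets")
    common = set.intersection(*feature_sets)
    if not common:
        raise ValueError("feature intersection is empty")
    logger.info("intersect_features: %d shared genes", len(common))
    return pd.Index(sorted(common), name="gene_id")
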