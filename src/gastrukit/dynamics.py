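"""Pseudotime expression dynamics and cross-dataset conservation.

Genes are tested for pseudotime-dependent expression with a likelihood-ratio
test between a negative-binomial GLM on a natural cubic spline basis of
pseudotime (with a log library-size offset) and the intercept-only model;
Benjamini-Hochberg q-values below 0.05 define DEGs.  Pseudotime itself is an
input (a per-cell scalar from any trajectory method).

Gene dynamics are represented as per-gene z-scored mean expression over
equal-occupancy pseudotime bins; Ward hierarchical clustering splits them
into an up- and a down-regulated group, and DEGs of a focal dataset are
classified against a second dataset into six categories: up-up, down-down,
up-down, down-up, up-unexpressed and down-unexpressed ("unexpressed" = the
ortholog counterpart is not detected in the other dataset).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .containers import OrthologMap

logger = logging.getLogger(__name__)

__all__ = [
    "natural_spline_basis",
    "deg_along_pseudotime",
    "bin_and_smooth",
    "label_direction",
    "detected_genes",
    "classify_conservation",
    "ConservationTable",
    "rank_pseudotime",
]

CONSERVED = ("up-up", "down-down")


def natural_spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis (no intercept column) with ``df`` columns.

    Knots are placed at quantiles of ``x``; the basis is the standard
    truncated-power construction with linear extrapolation beyond the
    boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1:
        return x[:, None]
    n_knots = df + 1
    knots = np.quantile(x, np.linspace(0, 1, n_knots))
    knots = np.unique(knots)
    if len(knots) < 3:  # not enough distinct values for curvature
        return x[:, None]
    kK, kK1 = knots[-1], knots[-2]

    def d(k):
        return (
            np.clip(x - k, 0, None) ** 3 - np.clip(x - kK, 0, None) ** 3
        ) / (kK - k)

    cols = [x]
    dK1 = d(kK1)
    for k in knots[:-2]:
        cols.append(d(k) - dK1)
    return np.column_stack(cols)


def _fit_nb_lrt(y, X_full, offset):
    """LRT p-value of the spline terms in an NB GLM with moment-estimated
    dispersion; falls back to (quasi-)Poisson when estimation fails."""
    X_null = np.ones((len(y), 1))
    try:
        pois = sm.GLM(y, X_full, family=sm.families.Poisson(), offset=offset).fit()
        mu = pois.fittedvalues
        alpha = float(np.sum((y - mu) ** 2 - mu) / np.sum(mu**2))
        alpha = min(max(alpha, 1e-8), 10.0)
        fam = sm.families.NegativeBinomial(alpha=alpha)
        full = sm.GLM(y, X_full, family=fam, offset=offset).fit()
        null = sm.GLM(y, X_null, family=fam, offset=offset).fit()
        stat = 2.0 * (full.llf - null.llf)
        dof = X_full.shape[1] - 1
        return float(chi2.sf(max(stat, 0.0), dof))
    except Exception:  # noqa: BLE001 - non-convergent gene counts
        return 1.0


def deg_along_pseudotime(
    counts: pd.DataFrame,
    pseudotime: pd.Series,
    df: int = 3,
    alpha: float = 0.05,
    lib_size: pd.Series | None = None,
) -> pd.DataFrame:
    """Test each gene for pseudotime dependence.

    ``counts`` is genes x cells (raw); ``pseudotime`` is per cell.  Returns a
    frame with ``p_value``, ``q_value`` and ``deg`` per gene; all-zero genes
    get p = 1.
    """
    cells = counts.columns.intersection(pseudotime.index)
    if len(cells) < 50:
        raise ValueError("need at least 50 cells with pseudotime")
    t = pseudotime.loc[cells].to_numpy(float)
    if not np.isfinite(t).all():
        raise ValueError("pseudotime must be finite")
    mat = counts[cells].to_numpy(float)
    if lib_size is None:
        lib = mat.sum(axis=0)
    else:
        lib = lib_size.loc[cells].to_numpy(float)
    offset = np.log(np.maximum(lib, 1.0))
    basis = natural_spline_basis(t, df=df)
    X_full = np.column_stack([np.ones(len(t)), basis])
    pvals = np.ones(len(counts))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, y in enumerate(mat):
            if y.sum() == 0:
                continue
            pvals[i] = _fit_nb_lrt(y, X_full, offset)
    rej, q, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {"p_value": pvals, "q_value": q, "deg": rej}, index=counts.index
    )


def bin_and_smooth(
    counts: pd.DataFrame,
    pseudotime: pd.Series,
    n_bins: int = 20,
    scale: float = 1e4,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene z-scored mean expression over equal-occupancy pseudotime bins.

    Expression is depth-normalized and log1p-transformed per cell before
    binning; empty bins are filled by linear interpolation.  Returns the
    genes x bins profile frame and a flag series marking zero-variance genes
    (their profile is all zeros).
    """
    if n_bins < 5:
        raise ValueError("need at least 5 bins")
    cells = counts.columns.intersection(pseudotime.index)
    if len(cells) < n_bins:
        raise ValueError("fewer cells than bins")
    t = pseudotime.loc[cells]
    mat = counts[cells].to_numpy(float)
    lib = np.maximum(mat.sum(axis=0), 1.0)
    logged = np.log1p(mat / lib * scale)
    order = np.argsort(t.to_numpy(), kind="stable")
    ranks = np.empty(len(cells), dtype=int)
    ranks[order] = np.arange(len(cells))
    bins = (ranks * n_bins) // len(cells)
    prof = np.full((len(counts), n_bins), np.nan)
    for b in range(n_bins):
        mask = bins == b
        if mask.any():
            prof[:, b] = logged[:, mask].mean(axis=1)
    # interpolate any empty bins
    for row in prof:
        nans = np.isnan(row)
        if nans.any():
            row[nans] = np.interp(
                np.flatnonzero(nans), np.flatnonzero(~nans), row[~nans]
            )
    mean = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, ddof=1, keepdims=True)
    flat = (sd <= 1e-12).ravel()
    sd[sd <= 1e-12] = 1.0
    z = (prof - mean) / sd
    z[flat] = 0.0
    profiles = pd.DataFrame(
        z, index=counts.index, columns=[f"bin{b}" for b in range(n_bins)]
    )
    return profiles, pd.Series(flat, index=counts.index, name="zero_variance")


def label_direction(profiles: pd.DataFrame) -> pd.Series:
    """Split z-scored profiles into up/down groups by Ward clustering.

    Profiles are clustered (Ward linkage, Euclidean) into two groups; each
    group is labelled ``up`` if its centroid rises from first to last bin,
    else ``down``.  If both clusters move the same way (or only one gene is
    given), falls back to the per-gene sign with a warning.
    """
    arr = profiles.to_numpy(float)
    per_gene = np.where(arr[:, -1] - arr[:, 0] >= 0, "up", "down")
    if len(profiles) < 2:
        return pd.Series(per_gene, index=profiles.index, name="direction")
    Z = linkage(arr, method="ward")
    cl = fcluster(Z, 2, criterion="maxclust")
    labels = np.empty(len(arr), dtype=object)
    trends = {}
    for c in (1, 2):
        centroid = arr[cl == c].mean(axis=0)
        trends[c] = centroid[-1] - centroid[0]
    if np.sign(trends[1]) == np.sign(trends[2]):
        logger.warning("both clusters trend the same way; using per-gene sign")
        return pd.Series(per_gene, index=profiles.index, name="direction")
    for c in (1, 2):
        labels[cl == c] = "up" if trends[c] > 0 else "down"
    return pd.Series(labels, index=profiles.index, name="direction")


def detected_genes(counts: pd.DataFrame, min_cell_fraction: float = 0.01) -> set:
    """Genes with nonzero counts in at least ``min_cell_fraction`` of cells."""
    frac = (counts > 0).mean(axis=1)
    return set(counts.index[frac >= min_cell_fraction])


@dataclass
class ConservationTable:
    categories: pd.Series  # per focal DEG
    conserved_fraction: float  # over DEGs with detected counterparts
    conserved_fraction_all: float  # over all focal DEGs

    def counts(self) -> pd.Series:
        return self.categories.value_counts()


def classify_conservation(
    directions_focal: pd.Series,
    directions_other: pd.Series,
    detected_other: set,
    omap: OrthologMap | None = None,
    focal_species: int = 1,
) -> ConservationTable:
    """Six-category conservation classification of focal DEGs.

    ``directions_focal`` holds up/down labels for the focal dataset's DEGs;
    ``directions_other`` holds labels for genes of the other dataset (at
    least its detected counterparts).  Counterparts come from ``omap``
    (identity when None); many-to-many orthologs resolve by majority
    direction of detected counterparts, ties counting as discordant.
    """
    if omap is None:
        get_counterparts = lambda g: [g]  # noqa: E731
    else:
        direction = "to_species2" if focal_species == 1 else "to_species1"
        pairs = omap.mapping(direction)
        lut = pairs.groupby("source")["target"].apply(list)
        get_counterparts = lambda g: lut.get(g, [])  # noqa: E731
    cats = {}
    for gene, d in directions_focal.items():
        counterparts = [c for c in get_counterparts(gene) if c in detected_other]
        if not counterparts:
            cats[gene] = f"{d}-unexpressed"
            continue
        other_dirs = [directions_other.get(c) for c in counterparts]
        n_up = sum(1 for x in other_dirs if x == "up")
        n_down = sum(1 for x in other_dirs if x == "down")
        if n_up > n_down:
            other = "up"
        elif n_down > n_up:
            other = "down"
        else:  # tie: counts as discordant
            other = "down" if d == "up" else "up"
        cats[gene] = f"{d}-{other}"
    categories = pd.Series(cats, name="category")
    with_counterpart = ~categories.str.endswith("unexpressed")
    n_det = int(with_counterpart.sum())
    n_cons = int(categories[with_counterpart].isin(CONSERVED).sum())
    return ConservationTable(
        categories=categories,
        conserved_fraction=n_cons / n_det if n_det else np.nan,
        conserved_fraction_all=n_cons / len(categories) if len(categories) else np.nan,
    )


def rank_pseudotime(counts: pd.DataFrame) -> pd.Series:
    """Fixture fallback: pseudotime as the rank of cells along the first PC
    of log-normalized expression.  Not a substitute for trajectory inference."""
    mat = counts.to_numpy(float)
    lib = np.maximum(mat.sum(axis=0), 1.0)
    logged = np.log1p(mat / lib * 1e4)
    centred = logged - logged.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(centred.T, full_matrices=False)
    proj = centred.T @ vt[0]
    ranks = pd.Series(proj, index=counts.columns).rank(method="first")
    return (ranks - 1) / (len(ranks) - 1)
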