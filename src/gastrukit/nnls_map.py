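"""Reciprocal non-negative least-squares cell-type correspondence.

Each cell type `a` of dataset A (a depth-normalized, log1p pseudobulk
profile over marker genes) is predicted from the profiles of all cell types
of dataset B by NNLS with an intercept, giving coefficients beta_ab; the fit
is then repeated in the opposite direction for beta_ba.  The two directional
coefficients are combined per cell-type pair as

    beta = 2 * (beta_ab + 0.001) * (beta_ba + 0.001)

so that high values demand reciprocal, specific predictivity, and the
combined scores are z-scaled within each target cell type across candidates
before best-match assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .containers import CellMatrix, PseudobulkMatrix
from .preprocess import depth_normalize, pseudobulk

__all__ = [
    "CorrespondenceResult",
    "select_marker_genes",
    "nnls_fit",
    "combine_betas",
    "zscale_and_assign",
    "map_celltypes",
    "celltype_profiles",
]

BETA_PSEUDOCOUNT = 0.001
AMBIGUOUS_Z_GAP = 0.1


@dataclass
class CorrespondenceResult:
    """Directional NNLS coefficients and combined scores between two datasets."""

    beta_AB: pd.DataFrame  # rows: cell types of A (targets), cols: cell types of B
    beta_BA: pd.DataFrame  # rows: cell types of B (targets), cols: cell types of A
    combined: pd.DataFrame  # rows: A, cols: B
    zscaled: pd.DataFrame
    best_match: pd.DataFrame  # per A cell type: match, z, z_gap, ambiguous
    intercepts_A: pd.Series = None
    intercepts_B: pd.Series = None
    marker_genes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "celltypes_A": self.beta_AB.index.tolist(),
            "celltypes_B": self.beta_AB.columns.tolist(),
            "beta_AB": self.beta_AB.to_numpy().tolist(),
            "beta_BA": self.beta_BA.to_numpy().tolist(),
            "combined": self.combined.to_numpy().tolist(),
            "zscaled": self.zscaled.to_numpy().tolist(),
            "best_match": self.best_match.reset_index().to_dict(orient="records"),
        }


def celltype_profiles(cm: CellMatrix, scale: float = 1e4) -> pd.DataFrame:
    """Depth-normalized, log1p expression profile per cell type (genes x types)."""
    pb = pseudobulk(cm, group_by=("cell_type",))
    dn = depth_normalize(pb, scale=scale)
    profiles = np.log1p(dn.values)
    profiles.columns = pb.sample_meta["cell_type"].astype(str)
    return profiles


def select_marker_genes(
    target: str, profiles: pd.DataFrame, n_top: int = 200
) -> pd.Index:
    """Union of the top ``n_top`` most expressed and most specific genes.

    Specificity is the target's share of the summed per-cell-type means,
    among genes expressed in the target.  Ties break by gene-id order; if
    fewer than ``n_top`` genes exist, all are taken.
    """
    if target not in profiles.columns:
        raise KeyError(f"cell type {target!r} not found")
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    expr = profiles[target]
    total = profiles.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = (expr / total).where((expr > 0) & (total > 0), -np.inf)
    by_expr = expr.sort_index().sort_values(ascending=False, kind="stable").index[:n_top]
    spec_ranked = spec.sort_index().sort_values(ascending=False, kind="stable")
    spec_ranked = spec_ranked[spec_ranked > -np.inf]
    by_spec = spec_ranked.index[:n_top]
    return pd.Index(sorted(set(by_expr) | set(by_spec)), name="gene_id")


def nnls_fit(
    target: np.ndarray, predictors: np.ndarray, intercept: bool = True,
    nonneg_intercept: bool = True,
) -> tuple[float, np.ndarray, float]:
    """NNLS of one profile on a gene x cell-type predictor matrix.

    Minimizes ``||T - b0*1 - M b||^2`` with ``b >= 0``.  By default the
    intercept is an appended all-ones column constrained non-negative like
    the rest; with ``nonneg_intercept=False`` the fit runs on centred data
    and the intercept is unconstrained.  Returns ``(b0, b, residual_norm)``.
    """
    target = np.asarray(target, dtype=float)
    predictors = np.asarray(predictors, dtype=float)
    if predictors.ndim != 2 or len(target) != predictors.shape[0]:
        raise ValueError("target and predictors must share the gene axis")
    if len(target) == 0:
        raise ValueError("empty gene set")
    if not (np.isfinite(target).all() and np.isfinite(predictors).all()):
        raise ValueError("non-finite values in NNLS inputs")
    if not intercept:
        coef, rnorm = scipy.optimize.nnls(predictors, target)
        return 0.0, coef, rnorm
    if nonneg_intercept:
        design = np.hstack([np.ones((len(target), 1)), predictors])
        coef, rnorm = scipy.optimize.nnls(design, target)
        return float(coef[0]), coef[1:], rnorm
    tc = target - target.mean()
    pc = predictors - predictors.mean(axis=0, keepdims=True)
    coef, _ = scipy.optimize.nnls(pc, tc)
    b0 = float(target.mean() - predictors.mean(axis=0) @ coef)
    resid = target - b0 - predictors @ coef
    return b0, coef, float(np.linalg.norm(resid))


def combine_betas(beta_AB: pd.DataFrame, beta_BA: pd.DataFrame) -> pd.DataFrame:
    """Elementwise ``2 (beta_ab + 0.001)(beta_ba + 0.001)`` (A x B layout)."""
    a = beta_AB
    b = beta_BA.T  # align to rows A, cols B
    if not (a.index.equals(b.index) and a.columns.equals(b.columns)):
        raise ValueError("directional matrices are not conformable")
    if (a.to_numpy() < 0).any() or (b.to_numpy() < 0).any():
        raise ValueError("NNLS coefficients must be non-negative")
    return 2.0 * (a + BETA_PSEUDOCOUNT) * (b + BETA_PSEUDOCOUNT)


def zscale_and_assign(
    combined: pd.DataFrame, axis: str = "row"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """z-score combined scores and call the best match per target cell type.

    ``axis='row'`` (default) scales within each target across candidates;
    ``'column'`` and ``'matrix'`` are available as the scaling axis is a
    modelling choice.  Constant rows get z = 0 and are flagged.  The best
    match is the argmax z per row; matches whose z gap to the runner-up is
    below 0.1 are flagged ambiguous.
    """
    if combined.shape[1] < 2:
        raise ValueError("need at least 2 candidate cell types")
    arr = combined.to_numpy(float)
    if axis == "row":
        mean = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, ddof=1, keepdims=True)
    elif axis == "column":
        mean = arr.mean(axis=0, keepdims=True)
        sd = arr.std(axis=0, ddof=1, keepdims=True)
    elif axis == "matrix":
        mean = arr.mean()
        sd = arr.std(ddof=1)
        mean, sd = np.full_like(arr, mean), np.full_like(arr, sd)
    else:
        raise ValueError("axis must be 'row', 'column' or 'matrix'")
    sd = np.broadcast_to(np.asarray(sd, dtype=float), arr.shape).copy()
    mean = np.broadcast_to(np.asarray(mean, dtype=float), arr.shape)
    flat = sd <= 1e-12 * np.maximum(np.abs(mean), 1.0)
    sd[flat] = np.inf  # constant slices get z = 0
    z = (arr - mean) / sd
    zdf = pd.DataFrame(z, index=combined.index, columns=combined.columns)
    rows = []
    for ct, row in zdf.iterrows():
        order = row.sort_values(ascending=False)
        gap = float(order.iloc[0] - order.iloc[1])
        rows.append(
            {
                "target": ct,
                "match": order.index[0],
                "z": float(order.iloc[0]),
                "z_gap": gap,
                "ambiguous": gap < AMBIGUOUS_Z_GAP or bool(row.std(ddof=1) == 0),
            }
        )
    best = pd.DataFrame(rows).set_index("target")
    return zdf, best


def _directional_betas(
    profiles_target: pd.DataFrame,
    profiles_pred: pd.DataFrame,
    marker_sets: dict,
    nonneg_intercept: bool,
) -> tuple[pd.DataFrame, pd.Series]:
    betas, intercepts = {}, {}
    for ct in profiles_target.columns:
        genes = marker_sets[ct]
        t = profiles_target.loc[genes, ct].to_numpy()
        M = profiles_pred.loc[genes].to_numpy()
        b0, coef, _ = nnls_fit(t, M, intercept=True, nonneg_intercept=nonneg_intercept)
        betas[ct] = pd.Series(coef, index=profiles_pred.columns)
        intercepts[ct] = b0
    return pd.DataFrame(betas).T, pd.Series(intercepts)


def map_celltypes(
    cmA: CellMatrix,
    cmB: CellMatrix,
    omap=None,
    n_top: int = 200,
    zscale_axis: str = "row",
    marker_mode: str = "per_direction",
    nonneg_intercept: bool = True,
    scale: float = 1e4,
) -> CorrespondenceResult:
    """Full reciprocal-NNLS correspondence between two annotated datasets.

    If ``omap`` is given, dataset B is first converted into A's gene
    namespace.  Marker genes are selected per target cell type in its own
    dataset (``marker_mode='per_direction'``); ``'union'`` pools both
    directions' marker sets per pair of datasets.
    """
    profA = celltype_profiles(cmA, scale=scale)
    if omap is not None:
        from .features import convert_features

        pbB = pseudobulk(cmB, group_by=("cell_type",))
        conv = convert_features(pbB, omap, "to_species1")
        dn = depth_normalize(conv, scale=scale)
        profB = np.log1p(dn.values)
        profB.columns = pbB.sample_meta["cell_type"].astype(str)
    else:
        profB = celltype_profiles(cmB, scale=scale)
    shared = profA.index.intersection(profB.index)
    if not len(shared):
        raise ValueError("no shared genes between datasets")
    profA, profB = profA.loc[shared], profB.loc[shared]

    markers_A = {ct: select_marker_genes(ct, profA, n_top) for ct in profA.columns}
    markers_B = {ct: select_marker_genes(ct, profB, n_top) for ct in profB.columns}
    if marker_mode == "union":
        pooled = pd.Index(
            sorted(set().union(*markers_A.values(), *markers_B.values()))
        )
        markers_A = {ct: pooled for ct in markers_A}
        markers_B = {ct: pooled for ct in markers_B}
    elif marker_mode != "per_direction":
        raise ValueError("marker_mode must be 'per_direction' or 'union'")

    beta_AB, b0_A = _directional_betas(profA, profB, markers_A, nonneg_intercept)
    beta_BA, b0_B = _directional_betas(profB, profA, markers_B, nonneg_intercept)
    combined = combine_betas(beta_AB, beta_BA)
    zscaled, best = zscale_and_assign(combined, axis=zscale_axis)
    return CorrespondenceResult(
        beta_AB=beta_AB,
        beta_BA=beta_BA,
        combined=combined,
        zscaled=zscaled,
        best_match=best,
        intercepts_A=b0_A,
        intercepts_B=b0_B,
        marker_genes={"A": markers_A, "B": markers_B},
    )
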