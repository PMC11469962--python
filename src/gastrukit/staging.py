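"""Developmental staging on a reference principal-component time axis.

The reference (e.g. human embryos plus gastruloids spanning a developmental
window) is pseudobulked, normalized and decomposed by exact PCA.  Among the
top PCs, the one whose embedding best rank-correlates with known reference
stages is selected as the developmental-time axis (in practice the leading
PC often captures assay technology instead, so selection is by Spearman
correlation, not variance explained).  Query pseudobulks — other species or
embryo models, mapped through orthologs — are projected onto the reference
loadings and placed on a stage scale calibrated against per-stage medians of
the reference axis values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.isotonic import IsotonicRegression

from .containers import OrthologMap, PseudobulkMatrix
from .features import convert_features
from .preprocess import normalize_chain, pseudobulk

logger = logging.getLogger(__name__)

__all__ = [
    "StagingModel",
    "StageCalibration",
    "fit_reference",
    "fit_staging_model",
    "select_time_axis",
    "project",
    "calibrate",
    "assign_stage",
    "axis_values",
    "gene_axis_correlation",
    "stage_celltypes",
]


@dataclass
class StagingModel:
    """Fitted reference PC space plus the selected time axis.

    ``loadings`` is genes x PCs with orthonormal columns (sign fixed so each
    column's largest-magnitude entry is positive).  ``axis_index`` is 1-based.
    ``norm_mode`` controls projection: ``joint`` re-normalizes reference and
    query together (faithful to the original procedure, at the cost of
    letting queries shift reference gene statistics), ``frozen`` applies the
    stored per-gene statistics to the query alone.
    """

    features: pd.Index
    n_pcs: int
    loadings: pd.DataFrame  # genes x PC1..PCn
    reference_embeddings: pd.DataFrame  # samples x PC1..PCn
    axis_index: int | None = None
    axis_orientation: int = 1
    axis_correlations: pd.Series | None = None
    norm_mode: str = "joint"
    frozen_mean: pd.Series | None = None
    frozen_sd: pd.Series | None = None
    reference_raw: pd.DataFrame | None = None  # genes x samples, raw counts
    scale: float = 1e4

    @property
    def pc_names(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.n_pcs)]

    def axis_column(self) -> str:
        if self.axis_index is None:
            raise ValueError("time axis not selected yet")
        return f"PC{self.axis_index}"

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "features": self.features.tolist(),
            "n_pcs": self.n_pcs,
            "loadings": self.loadings.to_numpy().tolist(),
            "reference_sample_ids": self.reference_embeddings.index.tolist(),
            "reference_embeddings": self.reference_embeddings.to_numpy().tolist(),
            "axis_index": self.axis_index,
            "axis_orientation": self.axis_orientation,
            "axis_correlations": (
                None if self.axis_correlations is None else self.axis_correlations.tolist()
            ),
            "norm_mode": self.norm_mode,
            "frozen_mean": None if self.frozen_mean is None else self.frozen_mean.tolist(),
            "frozen_sd": None if self.frozen_sd is None else self.frozen_sd.tolist(),
            "reference_raw": (
                None
                if self.reference_raw is None
                else {
                    "columns": self.reference_raw.columns.tolist(),
                    "values": self.reference_raw.to_numpy().tolist(),
                }
            ),
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StagingModel":
        features = pd.Index(d["features"], name="gene_id")
        pc_names = [f"PC{i + 1}" for i in range(d["n_pcs"])]
        model = cls(
            features=features,
            n_pcs=d["n_pcs"],
            loadings=pd.DataFrame(d["loadings"], index=features, columns=pc_names),
            reference_embeddings=pd.DataFrame(
                d["reference_embeddings"],
                index=pd.Index(d["reference_sample_ids"]),
                columns=pc_names,
            ),
            axis_index=d["axis_index"],
            axis_orientation=d["axis_orientation"],
            norm_mode=d["norm_mode"],
            scale=d["scale"],
        )
        if d["axis_correlations"] is not None:
            model.axis_correlations = pd.Series(d["axis_correlations"], index=pc_names)
        if d["frozen_mean"] is not None:
            model.frozen_mean = pd.Series(d["frozen_mean"], index=features)
            model.frozen_sd = pd.Series(d["frozen_sd"], index=features)
        if d["reference_raw"] is not None:
            model.reference_raw = pd.DataFrame(
                d["reference_raw"]["values"],
                index=features,
                columns=pd.Index(d["reference_raw"]["columns"]),
            )
        return model


@dataclass
class StageCalibration:
    """Per-stage medians of the reference time-axis values."""

    stage_values: np.ndarray  # strictly increasing
    median_axis_value: np.ndarray
    stage_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.stage_values = np.asarray(self.stage_values, dtype=float)
        self.median_axis_value = np.asarray(self.median_axis_value, dtype=float)
        if not (np.diff(self.stage_values) > 0).all():
            raise ValueError("stage values must be strictly increasing")


def fit_reference(
    pb: PseudobulkMatrix,
    n_pcs: int = 7,
    reference_raw: pd.DataFrame | None = None,
    norm_mode: str = "joint",
    scale: float = 1e4,
) -> StagingModel:
    """Exact PCA (SVD) of the z-normalized sample x gene matrix.

    ``pb`` must be at the ``z`` stage.  Passing the raw reference matrix via
    ``reference_raw`` enables joint-mode projection and frozen statistics.
    Deterministic: PC signs are fixed so each loading column's
    largest-magnitude entry is positive.
    """
    if pb.stage != "z":
        raise ValueError("fit_reference expects a z-normalized pseudobulk matrix")
    X = pb.values.to_numpy().T  # samples x genes
    n_samples, n_genes = X.shape
    if n_pcs >= min(n_samples, n_genes):
        raise ValueError(
            f"n_pcs={n_pcs} must be < min(n_samples, n_genes) = {min(n_samples, n_genes)}"
        )
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    loadings = vt[:n_pcs].T  # genes x PCs
    # deterministic sign: largest-|loading| entry positive per column
    for k in range(n_pcs):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
    pc_names = [f"PC{i + 1}" for i in range(n_pcs)]
    loadings_df = pd.DataFrame(loadings, index=pb.gene_ids, columns=pc_names)
    embeddings = pd.DataFrame(X @ loadings, index=pb.sample_ids, columns=pc_names)
    model = StagingModel(
        features=pb.gene_ids,
        n_pcs=n_pcs,
        loadings=loadings_df,
        reference_embeddings=embeddings,
        norm_mode=norm_mode,
        scale=scale,
    )
    if reference_raw is not None:
        ref = reference_raw.loc[pb.gene_ids]
        model.reference_raw = ref
        logged = np.log1p(ref / ref.sum(axis=0) * scale)
        model.frozen_mean = logged.mean(axis=1)
        sd = logged.std(axis=1, ddof=1)
        model.frozen_sd = sd.where(sd > 0, 1.0)
    return model


def fit_staging_model(
    pb_raw: PseudobulkMatrix,
    features=None,
    n_pcs: int = 7,
    norm_mode: str = "joint",
    scale: float = 1e4,
) -> StagingModel:
    """Convenience wrapper: restrict to ``features``, normalize, fit."""
    values = pb_raw.values if features is None else pb_raw.values.loc[pd.Index(features)]
    pb = PseudobulkMatrix(values, pb_raw.sample_meta, stage="raw")
    pbz = normalize_chain(pb, scale=scale)
    return fit_reference(pbz, n_pcs=n_pcs, reference_raw=values, norm_mode=norm_mode, scale=scale)


def select_time_axis(
    model: StagingModel,
    stage_values: pd.Series,
    top_k: int = 7,
    exclude_pcs: tuple = (),
) -> StagingModel:
    """Pick the PC whose reference embedding best rank-correlates with stage.

    ``stage_values`` is indexed by reference sample id (samples with unknown
    stage are ignored).  Among the first ``top_k`` PCs (optionally excluding
    declared batch PCs), the axis is the PC of largest |Spearman r|, ties
    broken toward the lower index, oriented so the axis increases with stage.
    """
    stage_values = stage_values.dropna()
    common = model.reference_embeddings.index.intersection(stage_values.index)
    if stage_values.loc[common].nunique() < 3:
        raise ValueError("need at least 3 distinct stage values")
    emb = model.reference_embeddings.loc[common]
    stages = stage_values.loc[common].to_numpy(float)
    if np.ptp(stages) == 0:
        raise ValueError("all reference stages are equal")
    rs = []
    for pc in model.pc_names:
        r, _ = spearmanr(emb[pc].to_numpy(), stages)
        rs.append(r)
    corr = pd.Series(rs, index=model.pc_names, name="spearman_r")
    eligible = [
        i for i in range(min(top_k, model.n_pcs)) if (i + 1) not in tuple(exclude_pcs)
    ]
    if not eligible:
        raise ValueError("no eligible PCs for axis selection")
    abs_r = np.abs(corr.to_numpy())
    best = eligible[int(np.argmax(abs_r[eligible]))]  # argmax takes first on ties
    model.axis_correlations = corr
    model.axis_index = best + 1
    model.axis_orientation = 1 if corr.iloc[best] >= 0 else -1
    return model


def _joint_normalize(combined: pd.DataFrame, scale: float) -> pd.DataFrame:
    """normalize_chain on a genes x samples frame that may hold NaNs
    (features missing from the query); NaN z-scores are imputed as 0."""
    totals = np.nansum(combined.to_numpy(), axis=0)
    if (totals == 0).any():
        bad = combined.columns[totals == 0].tolist()
        raise ValueError(f"zero-total samples: {bad[:5]}")
    logged = np.log1p(combined / totals * scale)
    arr = logged.to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(arr, axis=1)
        sds = np.nanstd(arr, axis=1, ddof=1)
    sds = np.where(sds > 0, sds, 1.0)
    z = (arr - means[:, None]) / sds[:, None]
    z = np.nan_to_num(z, nan=0.0)
    return pd.DataFrame(z, index=combined.index, columns=combined.columns)


def project(
    model: StagingModel,
    query_pb: PseudobulkMatrix,
    omap: OrthologMap | None = None,
    direction: str = "to_species1",
    norm_mode: str | None = None,
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Project raw query pseudobulks into the reference PC space.

    The query is converted into the reference gene namespace through ``omap``
    (identity if None), checked for feature coverage, normalized (jointly
    with the stored reference, or against frozen statistics) and multiplied
    by the stored loadings.  Missing features enter as z = 0.
    Returns a samples x PC embedding frame with a ``feature_coverage``
    attribute in ``.attrs``.
    """
    mode = norm_mode or model.norm_mode
    if query_pb.stage != "raw":
        raise ValueError("project expects a raw query pseudobulk matrix")
    q = query_pb if omap is None else convert_features(query_pb, omap, direction)
    coverage = model.features.isin(q.gene_ids).mean()
    if coverage < min_coverage:
        raise ValueError(
            f"feature coverage {coverage:.3f} below required {min_coverage:.3f}"
        )
    qvals = q.values.reindex(model.features)
    if mode == "joint":
        if model.reference_raw is None:
            raise ValueError("joint projection requires the stored raw reference matrix")
        query_cols = qvals.columns
        ref = model.reference_raw
        overlap = query_cols.intersection(ref.columns)
        if len(overlap):
            qvals = qvals.rename(columns={c: f"query:{c}" for c in overlap})
            query_cols = qvals.columns
        combined = pd.concat([ref, qvals], axis=1)
        z = _joint_normalize(combined, model.scale)
        emb = pd.DataFrame(
            z.to_numpy().T @ model.loadings.to_numpy(),
            index=z.columns,
            columns=model.pc_names,
        )
        out = emb.loc[query_cols]
        if len(overlap):
            out = out.rename(index={f"query:{c}": c for c in overlap})
    elif mode == "frozen":
        if model.frozen_mean is None:
            raise ValueError("frozen projection requires stored per-gene statistics")
        totals = qvals.sum(axis=0, skipna=True)
        if (totals == 0).any():
            raise ValueError("zero-total query samples")
        logged = np.log1p(qvals / totals * model.scale)
        z = logged.sub(model.frozen_mean, axis=0).div(model.frozen_sd, axis=0)
        z = z.fillna(0.0)
        out = pd.DataFrame(
            z.to_numpy().T @ model.loadings.to_numpy(),
            index=qvals.columns,
            columns=model.pc_names,
        )
    else:
        raise ValueError("norm_mode must be 'joint' or 'frozen'")
    out.attrs["feature_coverage"] = float(coverage)
    return out


def axis_values(model: StagingModel, embeddings: pd.DataFrame) -> pd.Series:
    """Oriented time-axis coordinate for each embedded sample."""
    return model.axis_orientation * embeddings[model.axis_column()]


def calibrate(model: StagingModel, stage_values: pd.Series) -> StageCalibration:
    """Median reference axis value per stage (isotonic-adjusted if needed)."""
    stage_values = stage_values.dropna()
    common = model.reference_embeddings.index.intersection(stage_values.index)
    vals = axis_values(model, model.reference_embeddings.loc[common])
    stages = stage_values.loc[common].astype(float)
    if stages.nunique() < 2:
        raise ValueError("need at least 2 calibration stages")
    medians = vals.groupby(stages).median().sort_index()
    med = medians.to_numpy()
    if not (np.diff(med) > 0).all():
        logger.warning("stage medians not monotone in stage; applying isotonic adjustment")
        med = IsotonicRegression(increasing=True).fit_transform(medians.index.to_numpy(), med)
        # break exact ties so interpolation stays well defined
        for i in range(1, len(med)):
            if med[i] <= med[i - 1]:
                med[i] = med[i - 1] + 1e-9
    return StageCalibration(medians.index.to_numpy(), med)


def assign_stage(axis_vals: pd.Series, cal: StageCalibration) -> pd.DataFrame:
    """Piecewise-linear stage assignment against the calibration medians.

    Axis values beyond the calibrated range clamp to the end stages and are
    flagged ``beyond_range``.  ``nearest_reference_stage`` is the stage whose
    median axis value is closest.
    """
    vals = axis_vals.to_numpy(float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite axis values")
    assigned = np.interp(vals, cal.median_axis_value, cal.stage_values)
    beyond = (vals < cal.median_axis_value[0]) | (vals > cal.median_axis_value[-1])
    nearest_idx = np.abs(vals[:, None] - cal.median_axis_value[None, :]).argmin(axis=1)
    return pd.DataFrame(
        {
            "axis_value": vals,
            "assigned_stage": assigned,
            "nearest_reference_stage": cal.stage_values[nearest_idx],
            "beyond_range": beyond,
        },
        index=axis_vals.index.rename("sample_id"),
    )


def gene_axis_correlation(model: StagingModel, expr: pd.DataFrame) -> pd.Series:
    """Pearson r of each gene (rows of ``expr``, normalized scale) with the
    axis values of the matching samples; zero-variance genes get NaN."""
    emb = model.reference_embeddings
    common = expr.columns.intersection(emb.index)
    if not len(common):
        raise ValueError("no samples shared between expression and embeddings")
    av = axis_values(model, emb.loc[common]).to_numpy()
    X = expr[common].to_numpy(float)
    xc = X - X.mean(axis=1, keepdims=True)
    ac = av - av.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc @ ac / np.where(denom > 0, denom, 1.0), np.nan)
    return pd.Series(r, index=expr.index, name="pearson_r").sort_values()


def stage_celltypes(
    cm,
    model: StagingModel,
    cal: StageCalibration,
    omap: OrthologMap | None = None,
    direction: str = "to_species1",
    min_cells: int = 10,
    norm_mode: str | None = None,
) -> pd.DataFrame:
    """Stage each (sample, cell type) pseudobulk separately.

    Cell-type pseudobulks with fewer than ``min_cells`` aggregated cells are
    skipped (listed with ``skipped=True`` and no stage).
    """
    pb = pseudobulk(cm, group_by=("individual_id", "cell_type"))
    enough = pb.sample_meta["n_cells_aggregated"] >= min_cells
    skipped = pb.sample_meta.index[~enough]
    if not enough.any():
        report = pb.sample_meta[["individual_id", "cell_type", "n_cells_aggregated"]]
        report = report.rename(columns={"n_cells_aggregated": "n_cells"}).copy()
        report["skipped"] = True
        return report
    kept = PseudobulkMatrix(
        pb.values.loc[:, enough[enough].index], pb.sample_meta.loc[enough], stage="raw"
    )
    emb = project(model, kept, omap=omap, direction=direction, norm_mode=norm_mode)
    report = assign_stage(axis_values(model, emb), cal)
    report["individual_id"] = kept.sample_meta["individual_id"]
    report["cell_type"] = kept.sample_meta["cell_type"]
    report["n_cells"] = kept.sample_meta["n_cells_aggregated"]
    report["skipped"] = False
    if len(skipped):
        extra = pb.sample_meta.loc[skipped, ["individual_id", "cell_type", "n_cells_aggregated"]]
        extra = extra.rename(columns={"n_cells_aggregated": "n_cells"})
        extra["skipped"] = True
        report = pd.concat([report, extra])
    return report
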