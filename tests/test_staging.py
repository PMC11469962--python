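"""Reference PCA, time-axis selection, projection, calibration, assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from gastrukit import io as gio
from gastrukit.containers import PseudobulkMatrix
from gastrukit.preprocess import normalize_chain, pseudobulk
from gastrukit.staging import (
    StageCalibration,
    assign_stage,
    axis_values,
    calibrate,
    fit_reference,
    fit_staging_model,
    gene_axis_correlation,
    project,
    select_time_axis,
    stage_celltypes,
)


def _zpb(values, sample_ids=None):
    values = np.asarray(values, dtype=float)
    cols = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index([f"g{i}" for i in range(values.shape[0])], name="gene_id"),
                      columns=cols)
    return PseudobulkMatrix(df, pd.DataFrame(index=df.columns), stage="z")


@pytest.fixture(scope="module")
def ref_model(species_pair):
    _, cmA, _, _ = species_pair
    pbA = pseudobulk(cmA)
    model = fit_staging_model(pbA)
    stages = pbA.sample_meta["stage_value"].astype(float)
    model = select_time_axis(model, stages)
    return model, pbA, stages


class TestFitReference:
    def test_training_projection_reproduces_embeddings(self, ref_model):
        model, pbA, _ = ref_model
        z = normalize_chain(
            PseudobulkMatrix(model.reference_raw, pbA.sample_meta, stage="raw")
        )
        emb = z.values.to_numpy().T @ model.loadings.to_numpy()
        np.testing.assert_allclose(
            emb, model.reference_embeddings.to_numpy(), atol=1e-8
        )

    def test_loadings_orthonormal(self, ref_model):
        model, _, _ = ref_model
        L = model.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(model.n_pcs), atol=1e-10)

    def test_rank_one_data_pc1_dominates(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=12)
        v = rng.normal(size=30)
        X = np.outer(v, u) + 1e-6 * rng.normal(size=(30, 12))
        Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        # build an exactly rank-1 z matrix instead: v outer unit + jitter
        X = np.outer(v - v.mean(), u) / np.std(v, ddof=1)
        X += 1e-6 * rng.normal(size=X.shape)
        pb = _zpb(X.T)  # genes x samples
        model = fit_reference(pb, n_pcs=3)
        var = model.reference_embeddings.var(axis=0, ddof=1)
        assert var["PC1"] / var.sum() > 0.99

    def test_sample_order_permutation_invariant_loadings(self, species_pair):
        _, cmA, _, _ = species_pair
        pbA = pseudobulk(cmA)
        m1 = fit_staging_model(pbA)
        perm = np.random.default_rng(1).permutation(pbA.n_samples)
        pb2 = PseudobulkMatrix(
            pbA.values.iloc[:, perm], pbA.sample_meta.iloc[perm], stage="raw"
        )
        m2 = fit_staging_model(pb2)
        np.testing.assert_allclose(
            m1.loadings.to_numpy(), m2.loadings.to_numpy(), atol=1e-8
        )

    def test_n_pcs_bound(self):
        pb = _zpb(np.zeros((5, 4)))
        with pytest.raises(ValueError):
            fit_reference(pb, n_pcs=4)


class TestSelectTimeAxis:
    def _model_with_embeddings(self, emb):
        genes = pd.Index([f"g{i}" for i in range(8)], name="gene_id")
        pcs = [f"PC{i+1}" for i in range(emb.shape[1])]
        from gastrukit.staging import StagingModel

        return StagingModel(
            features=genes,
            n_pcs=emb.shape[1],
            loadings=pd.DataFrame(np.eye(8)[:, : emb.shape[1]], index=genes, columns=pcs),
            reference_embeddings=pd.DataFrame(
                emb, index=[f"s{i}" for i in range(emb.shape[0])], columns=pcs
            ),
        )

    def test_pc2_equals_stage(self):
        stages = pd.Series(
            np.arange(6, dtype=float), index=[f"s{i}" for i in range(6)]
        )
        rng = np.random.default_rng(2)
        emb = rng.normal(size=(6, 3))
        emb[:, 1] = stages.to_numpy()
        model = select_time_axis(self._model_with_embeddings(emb), stages)
        assert model.axis_index == 2
        assert model.axis_correlations["PC2"] == pytest.approx(1.0)
        assert model.axis_orientation == 1

    def test_negated_pc3_selected_and_flipped(self):
        stages = pd.Series(np.arange(8, dtype=float), index=[f"s{i}" for i in range(8)])
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(8, 4)) * 0.01
        emb[:, 2] = -stages.to_numpy()
        model = select_time_axis(self._model_with_embeddings(emb), stages)
        assert model.axis_index == 3
        assert model.axis_orientation == -1
        av = axis_values(model, model.reference_embeddings)
        assert spearmanr(av, stages).statistic == pytest.approx(1.0)
        # brute-force check: chosen PC has max |spearman| over all PCs
        abs_r = model.axis_correlations.abs()
        assert abs_r["PC3"] == abs_r.max()

    def test_tie_broken_toward_lower_index(self):
        stages = pd.Series(np.arange(6, dtype=float), index=[f"s{i}" for i in range(6)])
        emb = np.zeros((6, 3))
        emb[:, 0] = stages
        emb[:, 2] = stages  # identical |r| on PC1 and PC3
        emb[:, 1] = [0, 0, 1, 0, 1, 0]
        model = select_time_axis(self._model_with_embeddings(emb), stages)
        assert model.axis_index == 1

    def test_all_equal_stages_error(self):
        stages = pd.Series(np.ones(6), index=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError):
            select_time_axis(self._model_with_embeddings(np.zeros((6, 3))), stages)


class TestProject:
    def test_frozen_reference_sample_maps_to_itself(self, ref_model):
        model, pbA, _ = ref_model
        one = PseudobulkMatrix(
            pbA.values.iloc[:, [0]], pbA.sample_meta.iloc[[0]], stage="raw"
        )
        emb = project(model, one, norm_mode="frozen")
        np.testing.assert_allclose(
            emb.to_numpy().ravel(),
            model.reference_embeddings.iloc[0].to_numpy(),
            atol=1e-8,
        )

    def test_frozen_gene_mean_profile_is_origin(self, ref_model):
        import dataclasses

        model, pbA, _ = ref_model
        # a query whose depth-normalized values equal the frozen per-gene mean
        # profile has z = 0 everywhere, hence an all-zero embedding; the
        # normalization target must match the mean profile's own total
        mean_norm = np.expm1(model.frozen_mean)
        model2 = dataclasses.replace(model, scale=float(mean_norm.sum()))
        raw = np.round(mean_norm * 1e6).astype(int)
        q = PseudobulkMatrix(
            pd.DataFrame({"q": raw}, index=model.features),
            pd.DataFrame(index=["q"]),
            stage="raw",
        )
        emb = project(model2, q, norm_mode="frozen")
        assert np.abs(emb.to_numpy()).max() < 0.05

    def test_frozen_projection_affine(self, ref_model):
        model, _, _ = ref_model
        rng = np.random.default_rng(4)
        x = rng.normal(size=len(model.features))
        y = rng.normal(size=len(model.features))
        L = model.loadings.to_numpy()
        a = 0.3
        lhs = (a * x + (1 - a) * y) @ L
        rhs = a * (x @ L) + (1 - a) * (y @ L)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_low_coverage_rejected(self, ref_model):
        model, pbA, _ = ref_model
        few = PseudobulkMatrix(
            pbA.values.iloc[: len(model.features) // 2, :2],
            pbA.sample_meta.iloc[:2],
            stage="raw",
        )
        with pytest.raises(ValueError, match="coverage"):
            project(model, few)

    def test_query_stage_recovery_cross_species(self, species_pair, ref_model):
        _, _, cmB, omap = species_pair
        model, pbA, stages = ref_model
        pbB = pseudobulk(cmB)
        emb = project(model, pbB, omap=omap)
        truth = pbB.sample_meta["stage_value"].astype(float)
        r = spearmanr(axis_values(model, emb), truth).statistic
        assert r >= 0.8


class TestCalibrationAssignment:
    def _cal(self):
        return StageCalibration([1.0, 2.0, 3.0], [-2.0, 0.0, 4.0])

    def test_exact_median_maps_to_stage(self):
        rep = assign_stage(pd.Series([0.0], index=["q"]), self._cal())
        assert rep.loc["q", "assigned_stage"] == pytest.approx(2.0)
        assert not rep.loc["q", "beyond_range"]

    def test_midpoint_interpolates(self):
        rep = assign_stage(pd.Series([2.0], index=["q"]), self._cal())
        assert rep.loc["q", "assigned_stage"] == pytest.approx(2.5)
        assert rep.loc["q", "nearest_reference_stage"] in (2.0, 3.0)

    def test_beyond_range_clamped_and_flagged(self):
        rep = assign_stage(pd.Series([99.0, -99.0], index=["hi", "lo"]), self._cal())
        assert rep.loc["hi", "assigned_stage"] == 3.0
        assert rep.loc["lo", "assigned_stage"] == 1.0
        assert rep["beyond_range"].all()

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            assign_stage(pd.Series([np.nan]), self._cal())

    def test_non_monotone_medians_isotonically_adjusted(self, ref_model, caplog):
        model, _, stages = ref_model
        # scramble stages so medians cannot be monotone, expect a warning path
        bad = stages.copy()
        rng = np.random.default_rng(5)
        bad[:] = rng.permutation(bad.to_numpy())
        cal = calibrate(model, bad)
        assert (np.diff(cal.median_axis_value) > 0).all()


class TestGeneAxisCorrelation:
    def test_proportional_gene_r_one(self, ref_model):
        model, _, _ = ref_model
        av = axis_values(model, model.reference_embeddings)
        expr = pd.DataFrame(
            {"up": av.to_numpy() * 2 + 1, "down": -av.to_numpy()}
        ).T
        expr.columns = model.reference_embeddings.index
        r = gene_axis_correlation(model, expr)
        assert r["up"] == pytest.approx(1.0)
        assert r["down"] == pytest.approx(-1.0)

    def test_zero_variance_gene_missing(self, ref_model):
        model, _, _ = ref_model
        expr = pd.DataFrame(
            np.ones((1, model.reference_embeddings.shape[0])),
            index=["flat"],
            columns=model.reference_embeddings.index,
        )
        assert np.isnan(gene_axis_correlation(model, expr)["flat"])

    def test_random_gene_uncorrelated(self, ref_model):
        model, _, _ = ref_model
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(
            rng.normal(size=(200, model.reference_embeddings.shape[0])),
            columns=model.reference_embeddings.index,
        )
        r = gene_axis_correlation(model, expr)
        # null Pearson r with n=30: |r| > 0.6 is very unlikely
        assert (r.abs() > 0.6).mean() < 0.02


class TestStageCelltypes:
    def test_celltype_stages_close_to_sample_stages(self, species_pair, ref_model):
        _, cmA, _, _ = species_pair
        model, pbA, stages = ref_model
        cal = calibrate(model, stages)
        report = stage_celltypes(cmA, model, cal)
        ok = report[~report["skipped"]]
        whole = assign_stage(axis_values(model, model.reference_embeddings), cal)
        merged = ok.join(whole["assigned_stage"], on="individual_id", rsuffix="_whole")
        # shared time program: per-cell-type stages track whole-sample stages
        diffs = (merged["assigned_stage"] - merged["assigned_stage_whole"]).abs()
        assert diffs.median() < 0.5
        assert (diffs < 1.0).mean() > 0.9

    def test_small_celltypes_skipped(self, species_pair, ref_model):
        _, cmA, _, _ = species_pair
        model, _, stages = ref_model
        cal = calibrate(model, stages)
        cm = cmA.subset_cells(np.arange(5))
        cm.cell_meta["cell_type"] = [f"singleton{i}" for i in range(5)]
        report = stage_celltypes(cm, model, cal, min_cells=10)
        assert report["skipped"].all()

    def test_identical_cells_split_identically(self, species_pair, ref_model):
        import scipy.sparse as sp

        from gastrukit.containers import CellMatrix

        _, cmA, _, _ = species_pair
        model, pbA, stages = ref_model
        cal = calibrate(model, stages)
        sub = cmA.subset_cells(np.arange(100))
        meta1 = sub.cell_meta.copy()
        meta1["cell_type"] = "h1"
        meta2 = sub.cell_meta.copy()
        meta2["cell_type"] = "h2"
        meta2.index = pd.Index([f"{c}_dup" for c in meta2.index], name="cell_id")
        cm2 = CellMatrix(
            sp.hstack([sub.counts, sub.counts]),
            sub.gene_ids,
            pd.concat([meta1, meta2]),
        )
        rep = stage_celltypes(cm2, model, cal, min_cells=1)
        vals = rep.groupby("cell_type")["axis_value"].mean()
        assert vals["h1"] == pytest.approx(vals["h2"], abs=1e-9)


def test_model_json_roundtrip_preserves_projection(ref_model, species_pair, tmp_path):
    model, pbA, _ = ref_model
    _, _, cmB, omap = species_pair
    gio.write_staging_model(model, tmp_path / "model.json")
    back = gio.read_staging_model(tmp_path / "model.json")
    pbB = pseudobulk(cmB)
    e1 = project(model, pbB, omap=omap)
    e2 = project(back, pbB, omap=omap)
    np.testing.assert_allclose(e1.to_numpy(), e2.to_numpy(), atol=1e-12)
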