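"""Properties of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from gastrukit.preprocess import pseudobulk
from gastrukit.synthetic import (
    SyntheticCohortSpec,
    TimeProgram,
    default_cohort_spec,
    default_time_program,
    generate_annotated_dataset,
    generate_composition_cohort,
    generate_intensity_profile,
    generate_species_pair,
    generate_trajectory_genes,
)


def small_spec(**kw):
    defaults = dict(
        stages=(0.0, 1.0, 2.0, 3.0),
        n_individuals_per_stage=3,
        n_cells_per_individual=50,
        composition=(10.0, 10.0, 10.0, 10.0),
    )
    defaults.update(kw)
    return SyntheticCohortSpec(**defaults)


def test_species_pair_seeded_determinism():
    program = default_time_program(n_genes=100, seed=1)
    a1, b1, m1 = generate_species_pair(program, small_spec(), small_spec(species="speciesB"), seed=1)
    a2, b2, m2 = generate_species_pair(program, small_spec(), small_spec(species="speciesB"), seed=1)
    assert (a1.counts != a2.counts).nnz == 0
    assert (b1.counts != b2.counts).nnz == 0
    pd.testing.assert_frame_equal(m1.pairs, m2.pairs)


def test_cells_per_individual_conserved():
    program = default_time_program(n_genes=60, seed=2)
    cm = generate_annotated_dataset(program, small_spec(), seed=2)
    counts = cm.cell_meta.groupby("individual_id").size()
    assert (counts == 50).all()


def test_null_program_means_independent_of_stage():
    """With all time loadings zero, pseudobulk gene means do not trend with stage."""
    program = default_time_program(n_genes=150, time_fraction=0.0, tech_shift_sd=0.0, seed=3)
    assert (program.time_loadings == 0).all()
    cm = generate_annotated_dataset(
        program, small_spec(n_individuals_per_stage=5, n_cells_per_individual=100), seed=3
    )
    pb = pseudobulk(cm)
    dn = pb.values / pb.values.sum(axis=0)
    stages = pb.sample_meta["stage_value"].astype(float).to_numpy()
    rs = [pearsonr(dn.iloc[g], stages).statistic for g in range(len(dn))]
    # no systematic trend: mean correlation near 0, tails within Monte-Carlo error
    assert abs(np.mean(rs)) < 0.05
    assert np.mean(np.abs(rs) > 0.6) < 0.05


def test_loaded_genes_follow_closed_form_nb_expectation():
    """200 loaded genes (+0.5/stage) among flat ones: pseudobulk means rise
    strictly with stage and match the analytic library-share expectation."""
    n = 400
    loadings = np.zeros(n)
    loadings[:200] = 0.5
    baseline = np.full(n, 2.0)
    ct = pd.Index(["typeA", "typeB"], name="cell_type")
    program = TimeProgram(
        baseline=baseline,
        time_loadings=loadings,
        celltype_offsets=pd.DataFrame(np.zeros((2, n)), index=ct),
        dispersion=np.full(n, 8.0),
        tech_shift=np.zeros(n),
    )
    spec = small_spec(
        n_individuals_per_stage=5, composition=(5.0, 5.0), n_cells_per_individual=100
    )
    cm = generate_annotated_dataset(program, spec, seed=4)
    pb = pseudobulk(cm)
    shares = pb.values / pb.values.sum(axis=0)
    stage = pb.sample_meta["stage_value"].astype(float)
    mean_loaded_share = shares.iloc[:200].sum(axis=0).groupby(stage).mean()
    # closed form: loaded-gene share = 200 e^{0.5 t} / (200 e^{0.5 t} + 200)
    t = mean_loaded_share.index.to_numpy()
    expected = np.exp(0.5 * t) / (np.exp(0.5 * t) + 1.0)
    np.testing.assert_allclose(mean_loaded_share.to_numpy(), expected, atol=0.02)
    # mean log expression of loaded genes strictly increasing across stages
    log_loaded = np.log(shares.iloc[:200].mean(axis=0)).groupby(stage).mean()
    assert (np.diff(log_loaded.to_numpy()) > 0).all()


def test_negative_dispersion_rejected():
    with pytest.raises(ValueError, match="dispersion"):
        TimeProgram(
            baseline=np.zeros(3),
            time_loadings=np.zeros(3),
            celltype_offsets=pd.DataFrame(np.zeros((2, 3))),
            dispersion=np.array([1.0, -1.0, 1.0]),
            tech_shift=np.zeros(3),
        )


def test_ortholog_noise_fractions_validated():
    program = default_time_program(n_genes=50, seed=5)
    with pytest.raises(ValueError, match="fractions"):
        generate_species_pair(
            program, small_spec(), small_spec(species="speciesB"),
            ortholog_noise=(0.9, 0.2, 0.2), seed=5,
        )


def test_ortholog_map_structure():
    program = default_time_program(n_genes=300, seed=6)
    _, cmB, omap = generate_species_pair(
        program, small_spec(), small_spec(species="speciesB"),
        ortholog_noise=(0.8, 0.1, 0.1), seed=6,
    )
    per_source = omap.pairs.groupby("gene_species1").size()
    assert set(per_source.unique()) <= {1, 2}
    assert (per_source == 2).sum() > 0  # some 1:2 relations
    assert len(per_source) < 300  # some genes unmapped
    assert set(omap.pairs["gene_species2"]) <= set(cmB.gene_ids)


class TestCompositionCohort:
    def test_degenerate_concentration_near_uniform(self):
        cm = generate_composition_cohort(
            ["a", "b", "c"], (1e6, 1e6, 1e6), n_individuals=10, n_cells=300, seed=7
        )
        props = (
            cm.cell_meta.groupby("individual_id")["cell_type"]
            .value_counts(normalize=True)
            .unstack(fill_value=0)
        )
        # multinomial s.d. at p=1/3, n=300 is ~0.027
        assert (np.abs(props - 1 / 3) < 3 * 0.0273).all().all()

    def test_low_concentration_more_variable(self):
        def sd_of(conc, seed):
            cm = generate_composition_cohort(
                ["a", "b", "c"], conc, n_individuals=50, n_cells=200, seed=seed
            )
            props = (
                cm.cell_meta.groupby("individual_id")["cell_type"]
                .value_counts(normalize=True)
                .unstack(fill_value=0)
            )
            return props.std().mean()

        # Dirichlet variance alpha_i(alpha_0-alpha_i)/(alpha_0^2 (alpha_0+1))
        assert sd_of((1.0, 1.0, 1.0), 8) > sd_of((100.0, 100.0, 100.0), 9)

    def test_seeded_determinism(self):
        c1 = generate_composition_cohort(["a", "b"], (2.0, 2.0), 5, 50, seed=10)
        c2 = generate_composition_cohort(["a", "b"], (2.0, 2.0), 5, 50, seed=10)
        assert (c1.cell_meta["cell_type"] == c2.cell_meta["cell_type"]).all()
        assert (c1.counts != c2.counts).nnz == 0

    def test_too_few_cell_types_rejected(self):
        with pytest.raises(ValueError):
            generate_composition_cohort(["only"], (1.0,), 5, 50, seed=0)


class TestTrajectoryGenes:
    def test_noiseless_up_genes_monotone(self):
        dsA, _ = generate_trajectory_genes(10, 0, 0, n_cells=100, noise_sd=0.0, seed=11)
        vals = dsA.values.to_numpy()
        assert (np.diff(vals, axis=1) >= 0).all()

    def test_flat_genes_have_no_slope(self):
        dsA, _ = generate_trajectory_genes(0, 0, 40, n_cells=200, noise_sd=0.3, seed=12)
        t = dsA.pseudotime.to_numpy()
        tc = t - t.mean()
        slopes = (dsA.values.to_numpy() - dsA.values.to_numpy().mean(axis=1, keepdims=True)) @ tc / (tc @ tc)
        assert abs(np.mean(slopes)) < 0.1

    def test_seeded_determinism_and_planted_discordance(self):
        a1, b1 = generate_trajectory_genes(20, 20, 10, seed=13, concordance=0.8)
        a2, b2 = generate_trajectory_genes(20, 20, 10, seed=13, concordance=0.8)
        pd.testing.assert_frame_equal(a1.counts, a2.counts)
        pd.testing.assert_frame_equal(b1.counts, b2.counts)
        dyn = a1.truth != "flat"
        flipped = (a1.truth[dyn] != b1.truth[dyn]).sum()
        assert flipped == round(0.2 * dyn.sum())


class TestIntensityProfile:
    def test_zero_amplitude_flat(self):
        prof = generate_intensity_profile(500, 100.0, amplitude=0.0, seed=14)
        assert prof.intensity["ch1"].std() == 0

    def test_seeded_determinism(self):
        p1 = generate_intensity_profile(400, 80.0, noise_sd=0.1, seed=15)
        p2 = generate_intensity_profile(400, 80.0, noise_sd=0.1, seed=15)
        pd.testing.assert_frame_equal(p1.intensity, p2.intensity)

    def test_period_must_fit(self):
        with pytest.raises(ValueError):
            generate_intensity_profile(100, 200.0)
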