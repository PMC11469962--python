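"""Synthetic single-cell cohorts with planted developmental structure.

The generators emulate the statistical structure the downstream analyses
assume, without attempting to mimic real gene symbols or genome organisation:

* a shared latent developmental-time program expressed in two "species" with
  disjoint gene namespaces linked by a noisy many-to-many ortholog map;
* distinct per-cell-type expression offsets;
* a technology/batch axis stronger than the time axis, so that staging must
  find the time signal on a principal component other than PC1;
* Dirichlet-multinomial cell-type compositions across individuals;
* monotone gene trajectories along pseudotime; and
* periodic, anti-phase somite marker intensity profiles.

Counts are negative-binomial around ``exp(baseline + time_loading * t +
celltype_offset + tech_level * tech_shift)``, scaled to a lognormal per-cell
library size.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CellMatrix, IntensityProfile, OrthologMap

__all__ = [
    "TimeProgram",
    "SyntheticCohortSpec",
    "TrajectoryDataset",
    "default_time_program",
    "default_cohort_spec",
    "generate_species_pair",
    "generate_annotated_dataset",
    "generate_composition_cohort",
    "generate_trajectory_genes",
    "generate_intensity_profile",
]

# library sizes are lognormal(log 5e3, 0.3) unless overridden
DEFAULT_LIBSIZE_LOG_MEAN = math.log(5e3)
DEFAULT_LIBSIZE_LOG_SD = 0.3

# ortholog-map corruption: 90% 1:1, 5% 1:2, 5% unmapped
DEFAULT_ORTHOLOG_NOISE = (0.90, 0.05, 0.05)


@dataclass
class TimeProgram:
    """Gene-level parameters of the latent developmental-time program.

    All effects are on the log scale.  ``time_loadings`` is zero for
    time-independent genes; ``dispersion`` is the negative-binomial size
    parameter (smaller = more overdispersed); ``tech_shift`` is a single
    batch/technology axis whose per-sample strength is set by the cohort's
    ``tech_levels``.
    """

    baseline: np.ndarray
    time_loadings: np.ndarray
    celltype_offsets: pd.DataFrame  # cell types x genes
    dispersion: np.ndarray
    tech_shift: np.ndarray

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.time_loadings = np.asarray(self.time_loadings, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        self.tech_shift = np.asarray(self.tech_shift, dtype=float)
        n = self.n_genes
        for name in ("time_loadings", "dispersion", "tech_shift"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != n_genes")
        if self.celltype_offsets.shape[1] != n:
            raise ValueError("celltype_offsets must be cell types x genes")
        if (self.dispersion <= 0).any():
            raise ValueError("dispersion must be strictly positive")

    @property
    def n_genes(self) -> int:
        return len(self.baseline)

    @property
    def celltypes(self) -> pd.Index:
        return self.celltype_offsets.index


@dataclass
class SyntheticCohortSpec:
    """Sampling design for one species' cohort.

    ``stages`` are the latent-time values; each stage contributes
    ``n_individuals_per_stage`` individuals of ``n_cells_per_individual``
    cells.  ``tech_levels`` are cycled over individuals within each stage and
    multiply the program's ``tech_shift``.  ``composition`` is the Dirichlet
    concentration over cell types from which each individual's cell-type
    proportions are drawn.
    """

    stages: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
    n_individuals_per_stage: int = 5
    n_cells_per_individual: int = 200
    composition: tuple = (10.0, 10.0, 10.0, 10.0)
    tech_levels: tuple = (0.0, 1.0)
    species: str = "speciesA"
    model: str = "embryo"
    libsize_log_mean: float = DEFAULT_LIBSIZE_LOG_MEAN
    libsize_log_sd: float = DEFAULT_LIBSIZE_LOG_SD

    def __post_init__(self) -> None:
        if not all(b > a for a, b in zip(self.stages, self.stages[1:])):
            raise ValueError("stages must be strictly increasing")
        if self.n_individuals_per_stage < 1 or self.n_cells_per_individual < 1:
            raise ValueError("counts must be >= 1")
        if any(c <= 0 for c in self.composition):
            raise ValueError("Dirichlet concentrations must be > 0")


def default_time_program(
    n_genes: int = 600,
    n_celltypes: int = 4,
    time_fraction: float = 0.4,
    time_loading_sd: float = 0.3,
    tech_shift_sd: float = 1.2,
    offset_sd: float = 0.8,
    offset_fraction: float = 0.25,
    dispersion: float = 8.0,
    seed: int = 0,
) -> TimeProgram:
    """Draw a TimeProgram with the default planted structure.

    A ``time_fraction`` of genes carry nonzero time loadings; every gene
    carries a technology shift (drawn wider than the per-stage time step, so
    the batch axis dominates the leading principal component); each cell type
    has sparse expression offsets marking ~``offset_fraction`` of genes.
    """
    rng = np.random.default_rng(seed)
    # baseline high enough that log1p of depth-normalized pseudobulk stays
    # near-linear in the planted log-scale effects
    baseline = rng.normal(2.0, 0.8, n_genes)
    loadings = np.zeros(n_genes)
    n_time = int(round(time_fraction * n_genes))
    idx = rng.choice(n_genes, n_time, replace=False)
    loadings[idx] = rng.normal(0.0, time_loading_sd, n_time)
    offsets = np.zeros((n_celltypes, n_genes))
    for c in range(n_celltypes):
        marked = rng.random(n_genes) < offset_fraction
        offsets[c, marked] = rng.normal(0.0, offset_sd, marked.sum())
    tech = rng.normal(0.0, tech_shift_sd, n_genes)
    celltypes = pd.Index([f"type{c}" for c in range(n_celltypes)], name="cell_type")
    return TimeProgram(
        baseline=baseline,
        time_loadings=loadings,
        celltype_offsets=pd.DataFrame(offsets, index=celltypes),
        dispersion=np.full(n_genes, float(dispersion)),
        tech_shift=tech,
    )


def default_cohort_spec(species: str = "speciesA", **overrides) -> SyntheticCohortSpec:
    base = SyntheticCohortSpec(species=species)
    if species != "speciesA" and "tech_levels" not in overrides:
        # the query species is profiled with a single, different technology
        base = replace(base, tech_levels=(1.0,), model="gastruloid")
    return replace(base, **overrides)


def _simulate_cohort(
    program: TimeProgram,
    spec: SyntheticCohortSpec,
    gene_ids: pd.Index,
    rng: np.random.Generator,
) -> CellMatrix:
    """Draw one species' cells.  Counts for each cell are NB around the
    library-size-scaled program rate for its (stage, cell type, tech) stratum."""
    n_genes = program.n_genes
    ctypes = program.celltypes
    conc = np.asarray(spec.composition, dtype=float)
    if len(conc) != len(ctypes):
        raise ValueError("composition length must match number of cell types")
    blocks, meta_rows = [], []
    size = program.dispersion
    for stage in spec.stages:
        for i in range(spec.n_individuals_per_stage):
            tech = spec.tech_levels[i % len(spec.tech_levels)]
            ind = f"{spec.species}_t{stage:g}_i{i}"
            props = rng.dirichlet(conc)
            type_of_cell = rng.choice(len(ctypes), spec.n_cells_per_individual, p=props)
            libsizes = rng.lognormal(
                spec.libsize_log_mean, spec.libsize_log_sd, spec.n_cells_per_individual
            )
            counts = np.empty((spec.n_cells_per_individual, n_genes), dtype=np.int64)
            for c_idx in range(len(ctypes)):
                cells = np.flatnonzero(type_of_cell == c_idx)
                if not cells.size:
                    continue
                log_rate = (
                    program.baseline
                    + program.time_loadings * stage
                    + program.celltype_offsets.iloc[c_idx].to_numpy()
                    + tech * program.tech_shift
                )
                rate = np.exp(log_rate)
                rate /= rate.sum()
                mu = libsizes[cells, None] * rate[None, :]
                p = size / (size + mu)
                counts[cells] = rng.negative_binomial(size, p)
            blocks.append(counts)
            for c in range(spec.n_cells_per_individual):
                meta_rows.append(
                    (
                        f"{ind}_c{c}",
                        ind,
                        str(ctypes[type_of_cell[c]]),
                        f"t{stage:g}",
                        float(stage),
                        spec.species,
                        spec.model,
                        float(tech),
                    )
                )
    meta = pd.DataFrame(
        meta_rows,
        columns=[
            "cell_id",
            "individual_id",
            "cell_type",
            "stage_label",
            "stage_value",
            "species",
            "model",
            "tech_level",
        ],
    ).set_index("cell_id")
    counts = sp.csr_matrix(np.vstack(blocks).T)  # genes x cells
    return CellMatrix(counts, gene_ids, meta)


def generate_annotated_dataset(
    program: TimeProgram,
    spec: SyntheticCohortSpec,
    seed: int,
    gene_prefix: str = "GA",
) -> CellMatrix:
    """Single-species cohort with planted time/cell-type/tech structure."""
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"{gene_prefix}{i:04d}" for i in range(program.n_genes)], name="gene_id")
    return _simulate_cohort(program, spec, genes, rng)


def generate_species_pair(
    program: TimeProgram,
    specA: SyntheticCohortSpec,
    specB: SyntheticCohortSpec,
    ortholog_noise: tuple = DEFAULT_ORTHOLOG_NOISE,
    seed: int = 0,
) -> tuple[CellMatrix, CellMatrix, OrthologMap]:
    """Two cohorts sharing one latent program, in disjoint gene namespaces.

    ``ortholog_noise = (f_11, f_12, f_unmapped)`` controls the ortholog map:
    a fraction ``f_12`` of genes gain a second species-B paralog (retained in
    the map as a 1:2 relation) and ``f_unmapped`` are dropped from the map
    entirely.  Fractions must sum to <= 1; any remainder is treated as 1:1.
    """
    f11, f12, f_un = ortholog_noise
    if min(f11, f12, f_un) < 0 or f11 + f12 + f_un > 1 + 1e-9:
        raise ValueError("ortholog fractions must be non-negative and sum to <= 1")
    rng = np.random.default_rng(seed)
    n = program.n_genes
    genesA = pd.Index([f"GA{i:04d}" for i in range(n)], name="gene_id")
    genesB = pd.Index([f"GB{i:04d}" for i in range(n)], name="gene_id")

    # assign map classes before drawing cells so the layout is seed-stable
    classes = rng.choice(
        3, size=n, p=[1.0 - f12 - f_un, f12, f_un]
    )  # 0 = 1:1, 1 = 1:2, 2 = unmapped
    dup_idx = np.flatnonzero(classes == 1)

    cmA = _simulate_cohort(program, specA, genesA, rng)
    cmB = _simulate_cohort(program, specB, genesB, rng)

    if dup_idx.size:
        # species-B paralogs: independent NB redraw of the same gene program
        paralog_ids = pd.Index([f"GB{i:04d}P" for i in dup_idx])
        progP = TimeProgram(
            baseline=program.baseline[dup_idx],
            time_loadings=program.time_loadings[dup_idx],
            celltype_offsets=program.celltype_offsets.iloc[:, dup_idx],
            dispersion=program.dispersion[dup_idx],
            tech_shift=program.tech_shift[dup_idx],
        )
        # redraw paralog counts cell-by-cell, conditional on existing metadata
        paralog_counts = _redraw_counts(progP, cmB, rng)
        cmB = CellMatrix(
            sp.vstack([cmB.counts, sp.csr_matrix(paralog_counts)]),
            genesB.append(paralog_ids),
            cmB.cell_meta,
        )

    rows = []
    for i in range(n):
        if classes[i] == 2:
            continue
        rows.append((genesA[i], genesB[i]))
        if classes[i] == 1:
            rows.append((genesA[i], f"GB{i:04d}P"))
    omap = OrthologMap(pd.DataFrame(rows, columns=["gene_species1", "gene_species2"]))
    return cmA, cmB, omap


def _redraw_counts(program: TimeProgram, cm: CellMatrix, rng: np.random.Generator) -> np.ndarray:
    """NB counts for ``program``'s genes for every cell of ``cm`` (genes x cells)."""
    meta = cm.cell_meta
    per_cell_lib = np.asarray(cm.counts.sum(axis=0)).ravel().astype(float)
    per_cell_lib = np.maximum(per_cell_lib, 1.0)
    out = np.empty((program.n_genes, cm.n_cells), dtype=np.int64)
    ct_index = {str(c): i for i, c in enumerate(program.celltypes)}
    size = program.dispersion
    stage = meta["stage_value"].to_numpy(float)
    tech = meta["tech_level"].to_numpy(float)
    ct = meta["cell_type"].map(ct_index).to_numpy()
    for j in range(cm.n_cells):
        log_rate = (
            program.baseline
            + program.time_loadings * stage[j]
            + program.celltype_offsets.iloc[ct[j]].to_numpy()
            + tech[j] * program.tech_shift
        )
        mu = np.exp(log_rate)
        mu *= 0.05 * per_cell_lib[j] / mu.sum()  # paralogs carry ~5% of the library
        out[:, j] = rng.negative_binomial(size, size / (size + mu))
    return out


def generate_composition_cohort(
    cell_types,
    concentration,
    n_individuals: int,
    n_cells: int,
    seed: int,
    group: str = "group0",
    n_genes: int = 30,
) -> CellMatrix:
    """Cohort whose only planted structure is Dirichlet-multinomial composition.

    Each individual's cell-type proportions are drawn from a Dirichlet with
    the given concentration; cells are assigned multinomially.  A small count
    matrix with per-type expression offsets is attached so the object is a
    complete CellMatrix.
    """
    cell_types = list(cell_types)
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    concentration = np.asarray(concentration, dtype=float)
    if (concentration <= 0).any():
        raise ValueError("Dirichlet concentrations must be > 0")
    if len(concentration) != len(cell_types):
        raise ValueError("concentration length must match cell types")
    rng = np.random.default_rng(seed)
    baseline = rng.normal(1.0, 0.5, n_genes)
    offsets = rng.normal(0.0, 0.8, (len(cell_types), n_genes))
    blocks, meta_rows = [], []
    for i in range(n_individuals):
        ind = f"{group}_i{i}"
        props = rng.dirichlet(concentration)
        types = rng.choice(len(cell_types), n_cells, p=props)
        mu = np.exp(baseline[None, :] + offsets[types])
        counts = rng.poisson(mu)
        blocks.append(counts)
        for c in range(n_cells):
            meta_rows.append(
                (f"{ind}_c{c}", ind, cell_types[types[c]], "NA", np.nan, group, group, 0.0)
            )
    meta = pd.DataFrame(
        meta_rows,
        columns=[
            "cell_id",
            "individual_id",
            "cell_type",
            "stage_label",
            "stage_value",
            "species",
            "model",
            "tech_level",
        ],
    ).set_index("cell_id")
    genes = pd.Index([f"G{i:03d}" for i in range(n_genes)], name="gene_id")
    return CellMatrix(sp.csr_matrix(np.vstack(blocks).T), genes, meta)


@dataclass
class TrajectoryDataset:
    """One dataset of the paired trajectory fixture.

    ``values`` are continuous log-scale expressions (exactly monotone when
    ``noise_sd == 0``); ``counts`` are Poisson draws around ``exp(values)``
    suitable for the count-based pseudotime test; ``truth`` holds the planted
    per-gene direction labels (``up``/``down``/``flat``).
    """

    values: pd.DataFrame  # genes x cells
    counts: pd.DataFrame  # genes x cells, integer
    pseudotime: pd.Series  # per cell, in [0, 1]
    truth: pd.Series  # per gene


def generate_trajectory_genes(
    n_up: int,
    n_down: int,
    n_flat: int,
    n_cells: int = 300,
    noise_sd: float = 0.3,
    seed: int = 0,
    concordance: float = 1.0,
) -> tuple[TrajectoryDataset, TrajectoryDataset]:
    """Two paired expression-vs-pseudotime datasets with known direction labels.

    Gene g follows ``log mu = b0 + slope_g * t + eps``, with slope positive
    for "up" genes, negative for "down" genes and zero for "flat" genes.
    The second dataset reuses the same programs; a fraction ``1 -
    concordance`` of the up/down genes has its direction flipped there
    (planted discordance for the conservation classifier).
    """
    if min(n_up, n_down, n_flat) < 0:
        raise ValueError("gene counts must be >= 0")
    rng = np.random.default_rng(seed)
    n_genes = n_up + n_down + n_flat
    truth = pd.Series(
        ["up"] * n_up + ["down"] * n_down + ["flat"] * n_flat,
        index=pd.Index([f"TG{i:04d}" for i in range(n_genes)], name="gene_id"),
        name="direction",
    )
    slopes = np.concatenate(
        [
            rng.uniform(0.9, 1.6, n_up),
            -rng.uniform(0.9, 1.6, n_down),
            np.zeros(n_flat),
        ]
    )
    b0 = rng.normal(0.8, 0.3, n_genes)
    flip = np.zeros(n_genes, dtype=bool)
    dyn = np.flatnonzero(slopes != 0)
    if concordance < 1.0 and dyn.size:
        n_flip = int(round((1.0 - concordance) * dyn.size))
        flip[rng.choice(dyn, n_flip, replace=False)] = True

    def build(slope_vec, sub_seed):
        r = np.random.default_rng(sub_seed)
        t = np.sort(r.uniform(0.0, 1.0, n_cells))
        eps = r.normal(0.0, noise_sd, (n_genes, n_cells)) if noise_sd > 0 else 0.0
        values = b0[:, None] + slope_vec[:, None] * t[None, :] + eps
        counts = r.poisson(np.exp(values))
        cells = pd.Index([f"c{i:04d}" for i in range(n_cells)], name="cell_id")
        return TrajectoryDataset(
            values=pd.DataFrame(values, index=truth.index, columns=cells),
            counts=pd.DataFrame(counts, index=truth.index, columns=cells),
            pseudotime=pd.Series(t, index=cells, name="pseudotime"),
            truth=truth.copy(),
        )

    child = rng.integers(0, 2**31 - 1, 2)
    dsA = build(slopes, child[0])
    slopesB = np.where(flip, -slopes, slopes)
    dsB = build(slopesB, child[1])
    dsB.truth = pd.Series(
        np.select([slopesB > 0, slopesB < 0], ["up", "down"], "flat"),
        index=truth.index,
        name="direction",
    )
    return dsA, dsB


def generate_intensity_profile(
    n_positions: int,
    period: float,
    phase_offset: float = 0.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> IntensityProfile:
    """Two anti-phase sinusoidal intensity tracks (``ch1``, ``ch2``).

    Emulates mutually exclusive striping of rostral/caudal somite markers:
    ``ch1 = offset + A sin(2 pi x / period + phase)`` and ``ch2`` is shifted
    by half a period.  The noiseless difference signal after per-channel mean
    normalization has exactly ``floor(n_positions / period)`` maxima spaced
    one period apart.
    """
    if not period < n_positions:
        raise ValueError("period must be smaller than the number of positions")
    rng = np.random.default_rng(seed)
    x = np.arange(n_positions)
    offset = amplitude * 2.0 + 4.0 * noise_sd + 0.1
    phase = 2.0 * np.pi * x / period + phase_offset
    ch1 = offset + amplitude * np.sin(phase)
    ch2 = offset + amplitude * np.sin(phase + np.pi)
    if noise_sd > 0:
        ch1 = ch1 + rng.normal(0.0, noise_sd, n_positions)
        ch2 = ch2 + rng.normal(0.0, noise_sd, n_positions)
    ch1 = np.clip(ch1, 0.0, None)
    ch2 = np.clip(ch2, 0.0, None)
    return IntensityProfile(x, pd.DataFrame({"ch1": ch1, "ch2": ch2}))
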