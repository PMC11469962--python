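"""Inter-individual variability of cell-type composition.

The resampling scheme equalizes sequencing depth across individuals: a fixed
number of cells (default 100) is drawn without replacement from each
individual, independently several times (default 10) to form
pseudo-replicates.  For each cell type, the standard deviation of its
frequency across individuals is computed within each (group, replicate), and
a one-way ANOVA compares those s.d. values between groups, followed by
Tukey's HSD when significant.

Note that pseudo-replicates reuse the same individuals, so they are not
independent observations; the ANOVA inherits that dependence (see the
methods note).  The calibration of the procedure is therefore an empirical
question, measured by ``null_rejection_rate``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .containers import CellMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "subsample_compositions",
    "subsample_from_type_counts",
    "exclude_rare_celltypes",
    "compare_dispersion",
    "simulate_dirichlet_type_counts",
    "null_rejection_rate",
    "power_comparison",
]

DEFAULT_N_CELLS = 100
DEFAULT_N_REPS = 10


def _type_count_table(cm: CellMatrix) -> pd.DataFrame:
    """Individuals x cell types table of raw cell counts."""
    return (
        cm.cell_meta.groupby(["individual_id", "cell_type"], observed=True)
        .size()
        .unstack(fill_value=0)
        .sort_index()
    )


def subsample_from_type_counts(
    type_counts: pd.DataFrame,
    groups: pd.Series,
    n_cells: int = DEFAULT_N_CELLS,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
) -> pd.DataFrame:
    """Pseudo-replicate compositions from per-individual cell-type counts.

    Sampling ``n_cells`` cells without replacement from an individual whose
    type tally is ``k`` is a multivariate hypergeometric draw from ``k``.
    Individuals with fewer than ``n_cells`` cells are excluded with a log
    entry.  Returns a tidy frame with columns ``group``, ``individual_id``,
    ``replicate`` and one frequency column per cell type.
    """
    rng = np.random.default_rng(seed)
    totals = type_counts.sum(axis=1)
    eligible = totals >= n_cells
    dropped = type_counts.index[~eligible].tolist()
    if dropped:
        logger.info("excluded %d individuals with < %d cells: %s",
                    len(dropped), n_cells, dropped[:5])
    if not eligible.any():
        raise ValueError(f"no individual has >= {n_cells} cells")
    rows = []
    for ind in type_counts.index[eligible]:
        counts = type_counts.loc[ind].to_numpy(int)
        for rep in range(1, n_reps + 1):
            draw = rng.multivariate_hypergeometric(counts, n_cells)
            rows.append((groups.loc[ind], ind, rep, *(draw / n_cells)))
    out = pd.DataFrame(
        rows, columns=["group", "individual_id", "replicate", *type_counts.columns]
    )
    return out


def subsample_compositions(
    cm: CellMatrix,
    n_cells: int = DEFAULT_N_CELLS,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    group_col: str = "model",
) -> pd.DataFrame:
    """Pseudo-replicate compositions for every individual of a CellMatrix."""
    tc = _type_count_table(cm)
    groups = (
        cm.cell_meta.groupby("individual_id", observed=True)[group_col].first().loc[tc.index]
    )
    return subsample_from_type_counts(tc, groups, n_cells=n_cells, n_reps=n_reps, seed=seed)


def exclude_rare_celltypes(
    cm: CellMatrix, min_mean_per_individual: float = 1.0, group_col: str = "model"
) -> tuple[list, pd.DataFrame]:
    """Vocabulary filter: drop cell types too rare to support variance testing.

    A cell type whose mean raw count per individual falls below the threshold
    in any group is excluded (e.g. a type detected at < 1 cell per individual
    in one model).  Returns (retained cell types, exclusion report).
    """
    tc = _type_count_table(cm)
    groups = (
        cm.cell_meta.groupby("individual_id", observed=True)[group_col].first().loc[tc.index]
    )
    mean_by_group = tc.groupby(groups.values).mean()
    rows = []
    retained = []
    for ct in tc.columns:
        below = mean_by_group.index[mean_by_group[ct] < min_mean_per_individual].tolist()
        if below:
            rows.append({"cell_type": ct, "excluded": True,
                         "reason": f"mean count below {min_mean_per_individual} in {below}"})
        else:
            retained.append(ct)
            rows.append({"cell_type": ct, "excluded": False, "reason": ""})
    return retained, pd.DataFrame(rows).set_index("cell_type")


def compare_dispersion(
    runs: pd.DataFrame, celltypes=None, anova_alpha: float = 0.05
) -> pd.DataFrame:
    """Per-cell-type ANOVA of across-individual s.d. values between groups.

    ``runs`` is the tidy frame from :func:`subsample_compositions`.  For each
    cell type the s.d. of its frequency across individuals is computed within
    each (group, replicate); a one-way ANOVA compares groups, and Tukey's HSD
    runs only when the ANOVA p-value is below ``anova_alpha``.  Degenerate
    all-zero-variance cell types are flagged and skipped.  A BH-corrected
    q-value column across tested cell types is appended.
    """
    meta_cols = ["group", "individual_id", "replicate"]
    if celltypes is None:
        celltypes = [c for c in runs.columns if c not in meta_cols]
    groups = runs["group"].unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if runs["replicate"].nunique() < 2:
        raise ValueError("need at least 2 replicates")
    per_group_n = runs.groupby("group")["individual_id"].nunique()
    if (per_group_n < 2).any():
        bad = per_group_n[per_group_n < 2].index.tolist()
        raise ValueError(f"groups with a single individual: {bad}")

    records = []
    for ct in celltypes:
        sd = (
            runs.groupby(["group", "replicate"])[ct]
            .std(ddof=1)
            .rename("sd")
            .reset_index()
        )
        samples = [g["sd"].to_numpy() for _, g in sd.groupby("group")]
        rec = {
            "cell_type": ct,
            "mean_sd_by_group": {g: float(v["sd"].mean()) for g, v in sd.groupby("group")},
            "anova_p": np.nan,
            "tukey": None,
            "excluded": False,
            "reason": "",
        }
        if all(np.allclose(s, 0) for s in samples) or np.allclose(
            np.concatenate(samples).std(), 0
        ):
            rec["excluded"] = True
            rec["reason"] = "degenerate: zero variance in all groups"
        else:
            _, p = f_oneway(*samples)
            rec["anova_p"] = float(p)
            if p < anova_alpha:
                hsd = pairwise_tukeyhsd(sd["sd"].to_numpy(), sd["group"].to_numpy())
                frame = pd.DataFrame(
                    hsd.summary().data[1:], columns=hsd.summary().data[0]
                )
                rec["tukey"] = {
                    f"{r['group1']}|{r['group2']}": float(r["p-adj"])
                    for _, r in frame.iterrows()
                }
        records.append(rec)
    out = pd.DataFrame(records).set_index("cell_type")
    tested = out["anova_p"].notna()
    out["anova_q"] = np.nan
    if tested.any():
        out.loc[tested, "anova_q"] = multipletests(
            out.loc[tested, "anova_p"], method="fdr_bh"
        )[1]
    return out


# ---------------------------------------------------------------------------
# simulation helpers (calibration / power studies of the procedure itself)


def simulate_dirichlet_type_counts(
    concentration,
    n_individuals: int,
    n_cells_per_individual: int,
    rng: np.random.Generator,
    prefix: str = "ind",
) -> pd.DataFrame:
    """Per-individual cell-type tallies under a Dirichlet-multinomial cohort."""
    concentration = np.asarray(concentration, dtype=float)
    rows = {}
    for i in range(n_individuals):
        p = rng.dirichlet(concentration)
        rows[f"{prefix}{i}"] = rng.multinomial(n_cells_per_individual, p)
    cols = [f"type{i}" for i in range(len(concentration))]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


@dataclass
class NullCalibration:
    rejection_rate: float
    n_simulations: int
    n_tests: int
    alpha: float


def null_rejection_rate(
    concentration=(8.0, 8.0, 8.0),
    n_individuals: int = 10,
    n_cells_per_individual: int = 300,
    n_simulations: int = 1000,
    n_cells: int = DEFAULT_N_CELLS,
    n_reps: int = DEFAULT_N_REPS,
    alpha: float = 0.05,
    seed: int = 0,
) -> NullCalibration:
    """Empirical type-I error of the dispersion ANOVA under a shared Dirichlet.

    Two groups are drawn from the identical concentration each simulation;
    the fraction of per-cell-type ANOVAs with p < alpha estimates the actual
    size of the test (nominally ``alpha``; dependence between
    pseudo-replicates can inflate it).
    """
    rng = np.random.default_rng(seed)
    n_rej = n_tot = 0
    for s in range(n_simulations):
        tcs = []
        for gi, g in enumerate(("groupA", "groupB")):
            tc = simulate_dirichlet_type_counts(
                concentration, n_individuals, n_cells_per_individual, rng,
                prefix=f"{g}_i",
            )
            tc["__group"] = g
            tcs.append(tc)
        tc = pd.concat(tcs)
        groups = tc.pop("__group")
        runs = subsample_from_type_counts(
            tc, groups, n_cells=n_cells, n_reps=n_reps,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        res = compare_dispersion(runs, anova_alpha=alpha)
        tested = res["anova_p"].dropna()
        n_rej += int((tested < alpha).sum())
        n_tot += len(tested)
    return NullCalibration(n_rej / n_tot if n_tot else np.nan, n_simulations, n_tot, alpha)


@dataclass
class PowerComparison:
    anova_rejection_rate: float  # fraction of sims with p < alpha for all cell types
    sd_ordering_rate: float  # fraction where the variable group has larger mean s.d.
    n_simulations: int


def power_comparison(
    concentration_variable=(2.0, 2.0, 2.0),
    concentration_consistent=(50.0, 50.0, 50.0),
    n_individuals: int = 20,
    n_cells_per_individual: int = 300,
    n_simulations: int = 100,
    n_cells: int = DEFAULT_N_CELLS,
    n_reps: int = DEFAULT_N_REPS,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerComparison:
    """Power of the dispersion ANOVA against a true variability difference.

    A variable cohort (low Dirichlet concentration) is compared against a
    consistent one (high concentration); by the Dirichlet variance formula
    the variable group's across-individual s.d. is larger for every cell
    type, and the ANOVA should detect it.
    """
    rng = np.random.default_rng(seed)
    n_all_rej = n_order = 0
    for _ in range(n_simulations):
        tcs = []
        for g, conc in (("variable", concentration_variable),
                        ("consistent", concentration_consistent)):
            tc = simulate_dirichlet_type_counts(
                conc, n_individuals, n_cells_per_individual, rng, prefix=f"{g}_i"
            )
            tc["__group"] = g
            tcs.append(tc)
        tc = pd.concat(tcs)
        groups = tc.pop("__group")
        runs = subsample_from_type_counts(
            tc, groups, n_cells=n_cells, n_reps=n_reps,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        res = compare_dispersion(runs, anova_alpha=alpha)
        tested = res["anova_p"].dropna()
        if len(tested) and (tested < alpha).all():
            n_all_rej += 1
        ordering = all(
            rec["variable"] > rec["consistent"] for rec in res["mean_sd_by_group"]
        )
        n_order += int(ordering)
    return PowerComparison(
        n_all_rej / n_simulations, n_order / n_simulations, n_simulations
    )
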