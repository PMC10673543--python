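"""Self-validation studies: the quantitative checks behind the pipeline.

Each function re-runs a slice of the pipeline under controlled conditions
and returns the measured figure of merit: published-summary significance
tests, phantom pH-recovery error, ratiometric concentration robustness,
the endogenous-removal fixed point, statistical-machinery identities, and
the power of the cohort design.  The analysis drivers and the acceptance
checks call these; nothing here hard-codes an expected outcome.
"""

from __future__ import annotations

import numpy as np

from .bmsim import default_background_pools
from .calibration import IopamidolModel, build_calibration, build_pipeline_calibration
from .cestproc import process_stack_pair
from .cohortstats import SummaryStat, anova_bonferroni, summarize, t_test, t_test_from_summary
from .phantom import GroupEffect, PhantomSpec, default_protocol, generate_animal, generate_cohort
from .pipeline import process_animal

__all__ = [
    "PUBLISHED_SUMMARIES",
    "published_summary_tests",
    "ph_recovery_study",
    "noiseless_uniform_recovery",
    "concentration_independence",
    "endogenous_removal_check",
    "summary_vs_raw_t",
    "f_equals_t_squared",
    "bonferroni_familywise_error",
    "power_study",
    "survival_study",
]

#: published group summaries (mean, SD, n per arm) used as inputs to the
#: summary-statistic significance tests: excised tumor weight in grams and
#: tumor pHe after 1 and 2 weeks of treatment, control vs treated, n = 6
PUBLISHED_SUMMARIES = {
    "tumor_weight_g": ((1.16, 0.15, 6), (0.74, 0.09, 6)),
    "phe_week1": ((6.83, 0.02, 6), (6.76, 0.03, 6)),
    "phe_week2": ((6.89, 0.04, 6), (6.77, 0.04, 6)),
}


def published_summary_tests() -> dict:
    """Pooled unpaired t on each published control-vs-treated summary."""
    out = {}
    for name, ((m1, s1, n1), (m2, s2, n2)) in PUBLISHED_SUMMARIES.items():
        res = t_test_from_summary(
            SummaryStat("control", m1, s1, n1), SummaryStat("treated", m2, s2, n2)
        )
        out[name] = {"t": res.t, "df": res.df, "p": res.p}
    return out


def _study_protocol_model(curve_grid_step: float = 0.05):
    protocol = default_protocol()
    model = IopamidolModel()
    background = default_background_pools()
    grid = np.round(np.arange(6.0, 7.4001, curve_grid_step), 6)
    curve = build_pipeline_calibration(model, protocol, grid, background=background)
    return protocol, model, background, curve


def ph_recovery_study(
    n_phantoms: int = 20,
    seed: int = 0,
    snr: float = 40.0,
    matrix: tuple[int, int] = (64, 64),
    n_slices: int = 2,
    truth_range: tuple[float, float] = (6.6, 7.0),
) -> dict:
    """Recovered-vs-true mean pHe over a fleet of noisy phantoms.

    Truth means are drawn uniformly over ``truth_range``; each phantom is
    rendered at the stated SNR, processed by the full pipeline, and the
    recovered whole-tumor mean pHe compared to the ground truth.
    """
    protocol, model, background, curve = _study_protocol_model()
    rng = np.random.default_rng(seed)
    errors, coverages = [], []
    for i in range(n_phantoms):
        mu = float(rng.uniform(*truth_range))
        spec = PhantomSpec(
            matrix=matrix, n_slices=n_slices, tumor_semiaxes_mm=(6.0, 5.5, 3.0),
            ph_mean=mu, snr=snr, seed=int(rng.integers(2**31)),
        )
        scan = generate_animal(spec, protocol, model, background)
        res = process_animal(scan, curve)
        errors.append(res.qc["mean_pHe"] - scan.truth.mean_ph)
        coverages.append(res.qc["coverage"])
    errors = np.asarray(errors)
    return {
        "mae": float(np.abs(errors).mean()),
        "bias": float(errors.mean()),
        "errors": errors,
        "coverage_min": float(min(coverages)),
        "n_phantoms": n_phantoms,
    }


def noiseless_uniform_recovery(ph: float = 6.8, seed: int = 1) -> dict:
    """Absolute mean-pHe error on a uniform noiseless phantom."""
    protocol, model, background, curve = _study_protocol_model()
    spec = PhantomSpec(
        matrix=(64, 64), n_slices=2, tumor_semiaxes_mm=(6.0, 5.5, 3.0),
        ph_mean=ph, ph_gradient=0.0, heterogeneity_sd=0.0, snr=np.inf, seed=seed,
    )
    scan = generate_animal(spec, protocol, model, background)
    res = process_animal(scan, curve)
    return {
        "error": abs(res.qc["mean_pHe"] - scan.truth.mean_ph),
        "coverage": res.qc["coverage"],
    }


def concentration_independence(
    factors: tuple[float, ...] = (0.5, 2.0),
    ph_grid_step: float = 0.1,
) -> dict:
    """Relative calibration-ratio shift under agent-concentration scaling.

    Rebuilds the exact-physics calibration at scaled concentrations and
    reports the maximum relative ratio change over pH 6.0-7.4.
    """
    from dataclasses import replace
    from .bmsim import AcquisitionProtocol

    model = IopamidolModel()
    background = default_background_pools()
    proto2 = AcquisitionProtocol(
        3.0, 5.0, 7.0,
        (model.pool_42.chemical_shift, model.pool_55.chemical_shift),
    )
    grid = np.round(np.arange(6.0, 7.4001, ph_grid_step), 6)
    base = build_calibration(model, proto2, grid, background=background)
    max_shift = 0.0
    per_factor = {}
    for f in factors:
        scaled = build_calibration(
            replace(model, concentration=model.concentration * f),
            proto2, grid, background=background,
        )
        common = np.intersect1d(np.round(base.ph_grid, 6), np.round(scaled.ph_grid, 6))
        r0 = np.interp(common, base.ph_grid, base.ratio_grid)
        r1 = np.interp(common, scaled.ph_grid, scaled.ratio_grid)
        shift = float(np.max(np.abs(r1 - r0) / np.abs(r0)))
        per_factor[f] = shift
        max_shift = max(max_shift, shift)
    return {"max_relative_shift": max_shift, "per_factor": per_factor}


def endogenous_removal_check(seed: int = 2) -> dict:
    """Fixed point of the post-minus-pre subtraction.

    Identical stacks must give exactly zero contrast everywhere; a
    noiseless agent phantom must show strictly positive contrast at both
    label offsets inside the tumor.
    """
    protocol, model, background, curve = _study_protocol_model()
    spec = PhantomSpec(
        matrix=(32, 32), n_slices=1, tumor_semiaxes_mm=(5.0, 4.5, 2.0),
        ph_mean=6.8, snr=np.inf, seed=seed,
    )
    scan = generate_animal(spec, protocol, model, background)
    mask = scan.truth.tumor_mask
    offs = np.asarray(protocol.offsets)
    same = process_stack_pair(
        scan.pre.voxels, scan.pre.s0, scan.pre.voxels, scan.pre.s0, offs, mask
    )
    real = process_stack_pair(
        scan.pre.voxels, scan.pre.s0, scan.post.voxels, scan.post.s0, offs, mask
    )
    return {
        "max_abs_delta_identical": float(
            max(np.nanmax(np.abs(same[o]["delta"].values[mask])) for o in (4.2, 5.5))
        ),
        "min_delta_agent": float(
            min(np.nanmin(real[o]["delta"].values[mask]) for o in (4.2, 5.5))
        ),
    }


def summary_vs_raw_t(n_trials: int = 10, seed: int = 3) -> float:
    """Max |t_summary - t_raw| over simulated cohorts (identity check)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_trials):
        x = rng.normal(0.0, 1.0, int(rng.integers(4, 12)))
        y = rng.normal(0.3, 1.4, int(rng.integers(4, 12)))
        worst = max(worst, abs(t_test_from_summary(summarize(x), summarize(y)).t
                               - t_test(x, y).t))
    return worst


def f_equals_t_squared(seed: int = 4) -> float:
    """|F - t^2| for a two-group one-way ANOVA (algebraic identity)."""
    rng = np.random.default_rng(seed)
    x, y = rng.normal(0, 1, 8), rng.normal(0.6, 1.2, 9)
    return abs(anova_bonferroni([x, y])["F"] - t_test(x, y).t ** 2)


def bonferroni_familywise_error(
    n_reps: int = 1000, n_groups: int = 3, n: int = 6,
    alpha: float = 0.05, seed: int = 5,
) -> float:
    """Simulated family-wise error of Bonferroni pairwise tests under the null."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        groups = [rng.normal(0.0, 1.0, n) for _ in range(n_groups)]
        res = anova_bonferroni(groups)
        hits += any(c["p_adj"] < alpha for c in res["comparisons"])
    return hits / n_reps


def power_study(
    n_reps: int = 100,
    seed: int = 6,
    effect: float = 0.12,
    n_per_group: int = 6,
    heterogeneity_sd: float = 0.04,
    matrix: tuple[int, int] = (32, 32),
    alpha: float = 0.001,
) -> dict:
    """Pipeline-level power of the two-arm imaging design.

    Mirrors the headline week-2 contrast: control tumors at pHe ~6.77,
    treatment shifting the mean by ``effect``.  Each replicate renders and
    processes all animals of both arms at reduced matrix size and applies
    the pooled t-test to the recovered per-animal mean pHe.  Returns the
    fraction of replicates significant at ``alpha`` (two-sided).
    """
    protocol, model, background, curve = _study_protocol_model()
    template = PhantomSpec(
        matrix=matrix, n_slices=1, tumor_semiaxes_mm=(5.0, 4.5, 2.0),
        ph_mean=6.77, heterogeneity_sd=heterogeneity_sd, snr=40.0,
    )
    effects = {"control": GroupEffect(0.0), "treated": GroupEffect(effect)}
    ss = np.random.SeedSequence(seed)
    pvals = []
    for rep_seq in ss.spawn(n_reps):
        rep_seed = int(rep_seq.generate_state(1)[0] % (2**31))
        cohort = generate_cohort(template, n_per_group, effects, seed=rep_seed)
        means = {"control": [], "treated": []}
        for animal in cohort.animals:
            scan = generate_animal(animal.spec, protocol, model, background)
            res = process_animal(scan, curve)
            means[animal.group].append(res.qc["mean_pHe"])
        pvals.append(t_test(means["control"], means["treated"]).p)
    pvals = np.asarray(pvals)
    return {
        "fraction_significant": float((pvals < alpha).mean()),
        "median_p": float(np.median(pvals)),
        "n_reps": n_reps,
    }


def survival_study(seed: int = 7, n_per_group: int = 6) -> dict:
    """Log-rank comparison of a treated-vs-control digital cohort.

    Control tumors grow faster and hit the size endpoint earlier; reports
    the Kaplan-Meier log-rank p for the simulated two-arm study.
    """
    from .cohortstats import km_survival

    template = PhantomSpec(matrix=(16, 16), n_slices=1,
                           tumor_semiaxes_mm=(2.5, 2.0, 1.0))
    effects = {"control": GroupEffect(0.0, 0.25), "treated": GroupEffect(0.12, 0.16)}
    cohort = generate_cohort(template, n_per_group, effects, seed=seed)
    res = km_survival(cohort.table)
    return {"p": res["p"], "statistic": res["statistic"]}
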