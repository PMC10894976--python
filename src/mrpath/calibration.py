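"""Monte-Carlo calibration experiments over the synthetic scenarios.

Each function replays a named scenario under many seeds and measures one
operating characteristic of the estimators: type-I error of random-effects
IVW under the global null, recovery of the total effect and the mediated
proportion under partial mediation, power of the Egger intercept against
directional pleiotropy, MR-PRESSO's hit rate on a planted outlier, the
Steiger test's ability to call a reversed causal direction, and the
delta-method CI's agreement with a parametric bootstrap.

All experiments derive their per-replicate seeds from a single master seed,
so results are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from .estimators import egger, ivw
from .mediation import two_step_mediation
from .mvmr import mv_ivw
from .robustness import mr_presso, steiger_test
from .simulate import scenario_library, simulate_summary_stats

__all__ = [
    "replicate_seeds",
    "ivw_type1_error",
    "partial_mediation_recovery",
    "egger_intercept_detection",
    "presso_outlier_detection",
    "presso_null_calibration",
    "steiger_reverse_detection",
    "delta_method_check",
    "proportion_ci_coverage",
    "WORKED_EXAMPLE",
]

#: the worked mediation example: education -> smoking initiation -> gastric
#: ulcer scale (beta1 = -0.28 per SD of education; total = direct + b1*b2)
WORKED_EXAMPLE = {
    "beta1": -0.28, "se1": 0.028,
    "beta2": 0.62, "se2": 0.10,
    "total_effect": -0.4845,
}


def replicate_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate seeds (< 2**31) from one master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n) % (2**31 - 1)


def _scenario(name: str, seed: int):
    return simulate_summary_stats(replace(scenario_library()[name], seed=int(seed)))


def ivw_type1_error(n_reps: int = 1000, seed: int = 0, alpha: float = 0.05) -> dict:
    """Rejection rate of random-effects IVW under the global-null scenario."""
    rejections = 0
    for s in replicate_seeds(seed, n_reps):
        d = _scenario("null", s)
        est = ivw(d.harmonized(), random_effects=True)
        rejections += est.pvalue < alpha
    return {"rate": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}


def partial_mediation_recovery(n_reps: int = 500, seed: int = 0) -> dict:
    """Recover the total effect and mediated proportion under partial mediation.

    Per replicate: total effect by IVW over the exposure instruments, beta1 by
    IVW exposure -> mediator, beta2 by MV-IVW of the outcome on
    (exposure, mediator) over all instruments, proportion = beta1*beta2/total.
    Returns means, Monte-Carlo SEs and the generating truths.
    """
    totals, props = [], []
    truth = None
    for s in replicate_seeds(seed, n_reps):
        d = _scenario("partial-mediation", s)
        truth = d.truth
        total = ivw(d.harmonized()).beta
        beta1 = ivw(d.harmonized(outcome="mediator")).beta
        mv = mv_ivw(d.harmonized(exposures=("exposure", "mediator"), instruments="all"))
        beta2 = next(e for e in mv if e.exposure == "mediator").beta
        totals.append(total)
        props.append(beta1 * beta2 / total)
    totals, props = np.asarray(totals), np.asarray(props)
    return {
        "total_mean": float(totals.mean()),
        "total_mc_se": float(totals.std(ddof=1) / np.sqrt(n_reps)),
        "total_true": float(truth.total_effect),
        "proportion_mean": float(props.mean()),
        "proportion_mc_se": float(props.std(ddof=1) / np.sqrt(n_reps)),
        "proportion_true": float(truth.mediation_proportion),
        "n_reps": n_reps,
        "totals": totals,
        "proportions": props,
    }


def egger_intercept_detection(n_reps: int = 500, seed: int = 0,
                              scenario: str = "directional-pleiotropy",
                              alpha: float = 0.05) -> dict:
    """Fraction of replicates where the Egger intercept p falls below alpha."""
    hits = 0
    for s in replicate_seeds(seed, n_reps):
        d = _scenario(scenario, s)
        est = egger(d.harmonized())
        hits += est.extras["egger_intercept_p"] < alpha
    return {"rate": hits / n_reps, "n_reps": n_reps, "scenario": scenario}


def presso_outlier_detection(n_reps: int = 200, seed: int = 0,
                             n_sim: int = 1000) -> dict:
    """Fraction of single-outlier replicates where PRESSO flags the plant."""
    seeds = replicate_seeds(seed, 2 * n_reps).reshape(2, n_reps)
    hits = 0
    corrected_closer = 0
    truth_total = None
    for s_data, s_presso in zip(*seeds):
        d = _scenario("single-outlier", s_data)
        truth_total = d.truth.total_effect
        res = mr_presso(d.harmonized(), n_sim=n_sim, seed=int(s_presso))
        if d.truth.outlier_id in res.outliers:
            hits += 1
            if abs(res.beta_corrected - truth_total) < abs(res.beta_raw - truth_total):
                corrected_closer += 1
    return {
        "rate": hits / n_reps,
        "corrected_closer_rate": corrected_closer / max(hits, 1),
        "n_reps": n_reps,
        "n_sim": n_sim,
        "truth_total": truth_total,
    }


def presso_null_calibration(n_reps: int = 200, seed: int = 0,
                            n_sim: int = 500) -> dict:
    """Fraction of clean-null replicates with a PRESSO global p below 0.05."""
    seeds = replicate_seeds(seed, 2 * n_reps).reshape(2, n_reps)
    small = 0
    for s_data, s_presso in zip(*seeds):
        cfg = replace(scenario_library()["single-outlier"], outlier_index=None,
                      outlier_effect=0.0, seed=int(s_data))
        d = simulate_summary_stats(cfg)
        res = mr_presso(d.harmonized(), n_sim=n_sim, seed=int(s_presso))
        small += res.global_p < 0.05
    return {"rate": small / n_reps, "n_reps": n_reps}


def steiger_reverse_detection(n_reps: int = 500, seed: int = 0) -> dict:
    """Fraction of reverse-causation replicates where Steiger calls the
    reversed direction (direction_correct is False)."""
    correct_calls = 0
    for s in replicate_seeds(seed, n_reps):
        d = _scenario("reverse-causation", s)
        res = steiger_test(d.harmonized(), d.config.n_exposure, d.config.n_outcome)
        correct_calls += not res.direction_correct
    return {"rate": correct_calls / n_reps, "n_reps": n_reps}


def delta_method_check(n_draws: int = 100_000, seed: int = 0,
                       example: dict | None = None) -> dict:
    """Delta-method proportion SE against a parametric-bootstrap oracle.

    Draws beta1* and beta2* from normals around the worked example's values
    and compares the empirical SD of beta1*beta2*/total with the delta SE.
    """
    ex = dict(example or WORKED_EXAMPLE)
    res = two_step_mediation(**ex)
    rng = np.random.default_rng(seed)
    b1 = rng.normal(ex["beta1"], ex["se1"], n_draws)
    b2 = rng.normal(ex["beta2"], ex["se2"], n_draws)
    boot = b1 * b2 / ex["total_effect"]
    boot_se = float(boot.std(ddof=1))
    return {
        "proportion": res.proportion,
        "delta_se": res.proportion_se,
        "bootstrap_se": boot_se,
        "relative_error": abs(res.proportion_se - boot_se) / boot_se,
        "n_draws": n_draws,
    }


def proportion_ci_coverage(n_reps: int = 1000, seed: int = 0,
                           example: dict | None = None) -> dict:
    """Coverage of the delta-method 95% CI for the mediated proportion.

    Each replicate draws estimated beta1/beta2 around the worked example's
    truths, forms the delta-method CI, and checks whether it covers the true
    proportion.
    """
    ex = dict(example or WORKED_EXAMPLE)
    true_prop = ex["beta1"] * ex["beta2"] / ex["total_effect"]
    rng = np.random.default_rng(seed)
    z95 = stats.norm.ppf(0.975)
    b1 = rng.normal(ex["beta1"], ex["se1"], n_reps)
    b2 = rng.normal(ex["beta2"], ex["se2"], n_reps)
    prop = b1 * b2 / ex["total_effect"]
    se = np.sqrt(b1**2 * ex["se2"] ** 2 + b2**2 * ex["se1"] ** 2) / abs(ex["total_effect"])
    covered = (prop - z95 * se <= true_prop) & (true_prop <= prop + z95 * se)
    return {"coverage": float(covered.mean()), "n_reps": n_reps,
            "true_proportion": float(true_prop)}
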