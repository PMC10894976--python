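"""Pleiotropy and directionality diagnostics: MR-PRESSO and the Steiger test.

MR-PRESSO compares each variant's observed outcome association against the
leave-one-out IVW prediction.  The weighted residual sum of squares is
referenced against a parametric simulation of the no-pleiotropy null to give a
global test; per-variant residuals give outlier p-values (Bonferroni across
variants), and the IVW estimate before/after outlier removal gives the
distortion test.

The Steiger test checks causal direction by comparing the instrument-explained
variance in the exposure against the outcome; under a correct exposure->outcome
model the instruments should explain more variance in the exposure.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .estimators import ivw
from .exceptions import InsufficientInstrumentsError, ValidationError
from .summary_data import HarmonizedSet

__all__ = ["PressoResult", "SteigerResult", "mr_presso", "steiger_test", "steiger_filter"]


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier, and distortion test results."""

    global_rss: float
    global_p: float
    outlier_pvalues: dict
    outliers: list
    beta_raw: float
    beta_corrected: float | None
    distortion_p: float | None
    n_sim: int

    def summary(self) -> str:
        lines = [
            "MR-PRESSO",
            f"  global RSS = {self.global_rss:.4g}, global p = {self.global_p:.4g}",
            f"  outliers   = {self.outliers or 'none'}",
            f"  IVW beta raw = {self.beta_raw:+.4f}",
        ]
        if self.beta_corrected is not None:
            lines.append(
                f"  IVW beta corrected = {self.beta_corrected:+.4f} "
                f"(distortion p = {self.distortion_p:.4g})"
            )
        return "\n".join(lines)


@dataclass
class SteigerResult:
    """Directionality test on instrument-explained variance."""

    r2_exposure: float
    r2_outcome: float
    direction_correct: bool
    steiger_p: float

    def summary(self) -> str:
        direction = "exposure -> outcome" if self.direction_correct else "outcome -> exposure"
        return (
            f"Steiger directionality: r2(exposure) = {self.r2_exposure:.4g}, "
            f"r2(outcome) = {self.r2_outcome:.4g}; inferred {direction} "
            f"(p = {self.steiger_p:.3g})"
        )


def _loo_ivw(bx, by, w):
    """Leave-one-out IVW slopes, vectorized over the left-out variant."""
    s1 = np.sum(w * bx * by)
    s2 = np.sum(w * bx**2)
    return (s1 - w * bx * by) / (s2 - w * bx**2)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    outlier_significance: float = 0.05,
    seed=None,
) -> PressoResult:
    """MR-PRESSO global/outlier/distortion analysis.

    Requires k >= 4 instruments and a single exposure.  Simulation p-values
    use the add-one rule (r+1)/(n_sim+1).  Outliers are variants whose
    per-variant simulation p falls below ``outlier_significance``
    Bonferroni-corrected across the k variants.
    """
    if h.n_exposures != 1:
        raise ValidationError("mr_presso expects a single exposure")
    if h.k < 4:
        raise InsufficientInstrumentsError(f"mr_presso needs k >= 4, got {h.k}")
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives very coarse simulation p-values", stacklevel=2)
    rng = np.random.default_rng(seed)

    bx, by = h.exposure_beta(), h.beta_outcome
    se_y = h.se_outcome
    w = 1.0 / se_y**2
    k = h.k

    beta_loo = _loo_ivw(bx, by, w)
    resid_obs = w * (by - beta_loo * bx) ** 2
    rss_obs = float(resid_obs.sum())

    # parametric null: outcome betas drawn around the leave-one-out predictions
    by_sim = rng.normal(beta_loo * bx, se_y, size=(n_sim, k))
    s1_sim = np.sum(w * bx * by_sim, axis=1, keepdims=True)
    s2 = np.sum(w * bx**2)
    beta_loo_sim = (s1_sim - w * bx * by_sim) / (s2 - w * bx**2)
    resid_sim = w * (by_sim - beta_loo_sim * bx) ** 2
    rss_sim = resid_sim.sum(axis=1)

    global_p = (np.sum(rss_sim >= rss_obs) + 1.0) / (n_sim + 1.0)
    pvals = (np.sum(resid_sim >= resid_obs, axis=0) + 1.0) / (n_sim + 1.0)
    outlier_pvalues = dict(zip(h.variant_ids, pvals.astype(float)))
    bonferroni = outlier_significance / k
    outliers = [v for v, p in outlier_pvalues.items() if p < bonferroni]

    beta_raw = ivw(h, random_effects=True).beta
    beta_corrected = None
    distortion_p = None
    if outliers and len(outliers) < k - 1:
        keep = np.array([v not in set(outliers) for v in h.variant_ids], bool)
        beta_corrected = ivw(h.subset(keep), random_effects=True).beta
        d_obs = abs(beta_raw - beta_corrected) / max(abs(beta_corrected), 1e-300)
        n_out = len(outliers)
        d_sim = np.empty(n_sim)
        for i in range(n_sim):
            drop = rng.choice(k, size=n_out, replace=False)
            mask = np.ones(k, bool)
            mask[drop] = False
            b_sub = float(np.sum(w[mask] * bx[mask] * by[mask])
                          / np.sum(w[mask] * bx[mask] ** 2))
            d_sim[i] = abs(beta_raw - b_sub) / max(abs(b_sub), 1e-300)
        distortion_p = float((np.sum(d_sim >= d_obs) + 1.0) / (n_sim + 1.0))

    return PressoResult(
        global_rss=rss_obs,
        global_p=float(global_p),
        outlier_pvalues=outlier_pvalues,
        outliers=outliers,
        beta_raw=float(beta_raw),
        beta_corrected=None if beta_corrected is None else float(beta_corrected),
        distortion_p=distortion_p,
        n_sim=n_sim,
    )


def _r2_from_t(beta, se, n):
    """Per-variant variance explained via the t-statistic approximation."""
    t2 = (np.asarray(beta, float) / np.asarray(se, float)) ** 2
    return t2 / (t2 + np.asarray(n, float) - 2.0)


def steiger_test(h: HarmonizedSet, n_exposure: int, n_outcome: int) -> SteigerResult:
    """Steiger directionality test on a harmonized exposure-outcome set.

    Variance explained per variant is approximated from the t-statistic,
    r2_j = t_j^2 / (t_j^2 + n - 2), summed over instruments per trait.  The
    p-value compares Fisher-z-transformed multiple correlations with the
    normal approximation.  For binary traits the approximation is applied on
    the observed (log-odds) scale and is approximate.
    """
    if h.n_exposures != 1:
        raise ValidationError("steiger_test expects a single exposure")
    if n_exposure <= 2 or n_outcome <= 2:
        raise ValidationError("sample sizes must exceed 2")
    r2_exp = float(np.clip(_r2_from_t(h.exposure_beta(), h.exposure_se(), n_exposure).sum(), 0, 1))
    r2_out = float(np.clip(_r2_from_t(h.beta_outcome, h.se_outcome, n_outcome).sum(), 0, 1))
    r_exp, r_out = np.sqrt(r2_exp), np.sqrt(r2_out)
    denom = np.sqrt(1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3))
    z = (np.arctanh(min(r_exp, 1 - 1e-15)) - np.arctanh(min(r_out, 1 - 1e-15))) / denom
    from scipy import stats

    p = float(2.0 * stats.norm.sf(abs(z)))
    return SteigerResult(
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        direction_correct=bool(r2_exp > r2_out),
        steiger_p=max(p, np.finfo(float).tiny),
    )


def steiger_filter(h: HarmonizedSet, n_exposure: int, n_outcome: int) -> np.ndarray:
    """Per-SNP Steiger mask: True where the variant explains more variance in
    the exposure than in the outcome.

    Used to purge instruments whose primary association is really with the
    other trait (e.g. exposure-driven SNPs leaking into a genetically
    correlated mediator's instrument set) before a reverse-direction MR.
    """
    if h.n_exposures != 1:
        raise ValidationError("steiger_filter expects a single exposure")
    r2_exp = _r2_from_t(h.exposure_beta(), h.exposure_se(), n_exposure)
    r2_out = _r2_from_t(h.beta_outcome, h.se_outcome, n_outcome)
    return r2_exp > r2_out
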