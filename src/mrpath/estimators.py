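"""Univariable two-sample MR estimators.

Given a harmonized set of k instruments for a single exposure, the estimators
here regress the per-SNP outcome associations on the exposure associations
(or combine the per-SNP Wald ratios):

* ``ivw`` — inverse-variance-weighted estimate: weighted least squares of
  beta_Y on beta_X through the origin with weights 1/se_Y^2.  The
  random-effects variant inflates the fixed-effects SE multiplicatively by
  max(1, sqrt(Q/(k-1))) where Q is Cochran's heterogeneity statistic.
* ``egger`` — the same regression with a free intercept; a nonzero intercept
  estimates directional pleiotropy.
* ``weighted_median`` / ``weighted_mode`` — robust estimators on the Wald
  ratios, consistent when >=50% of the weight (median) or the largest cluster
  (mode) comes from valid instruments.  Their SEs are parametric bootstrap.

A thin model class :class:`UnivariableMR` provides the fit() entry point and
returns :class:`MREstimate` results objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import InsufficientInstrumentsError, UndefinedRatioError, ValidationError
from .summary_data import HarmonizedSet

__all__ = [
    "MREstimate",
    "RatioSet",
    "UnivariableMR",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "weighted_mode",
    "ratio_set",
    "median_point",
    "mode_point",
    "instrument_strength",
    "InstrumentStrength",
    "results_frame",
]

_Z95 = stats.norm.ppf(0.975)
_TINY_P = np.finfo(float).tiny


def _pvalue(beta: float, se: float) -> float:
    if se <= 0:
        return _TINY_P
    return max(float(2.0 * stats.norm.sf(abs(beta / se))), _TINY_P)


@dataclass
class MREstimate:
    """A causal-effect estimate with its uncertainty and diagnostics.

    ``extras`` carries method-specific scalars (Cochran's Q, Egger intercept,
    random-effects scale, bootstrap draw count, ...).  For binary outcomes the
    exp-transformed odds-ratio fields are populated.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    exposure: str | None = None
    outcome: str | None = None
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_normal(cls, method, beta, se, n_snps, *, binary=False,
                    exposure=None, outcome=None, extras=None):
        beta, se = float(beta), float(se)
        lo, hi = beta - _Z95 * se, beta + _Z95 * se
        est = cls(
            method=method, beta=beta, se=se, ci_low=lo, ci_high=hi,
            pvalue=_pvalue(beta, se), n_snps=int(n_snps),
            exposure=exposure, outcome=outcome, extras=dict(extras or {}),
        )
        if binary:
            est.odds_ratio = float(np.exp(beta))
            est.or_ci_low = float(np.exp(lo))
            est.or_ci_high = float(np.exp(hi))
        return est

    def to_row(self) -> dict:
        row = {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
        }
        for key in ("cochran_q", "q_df", "q_pvalue", "re_scale",
                    "egger_intercept", "egger_intercept_se", "egger_intercept_p",
                    "conditional_f", "adjusted_for"):
            row[key] = self.extras.get(key)
        return row

    def summary(self) -> str:
        lines = [
            f"MR estimate [{self.method}]"
            + (f": {self.exposure} -> {self.outcome}" if self.exposure else ""),
            f"  n_snps = {self.n_snps}",
            f"  beta   = {self.beta:+.4f} (se {self.se:.4f})",
            f"  95% CI = [{self.ci_low:+.4f}, {self.ci_high:+.4f}]",
            f"  p      = {self.pvalue:.3g}",
        ]
        if self.odds_ratio is not None:
            lines.append(
                f"  OR     = {self.odds_ratio:.3f} "
                f"({self.or_ci_low:.3f}-{self.or_ci_high:.3f})"
            )
        for key in ("cochran_q", "q_pvalue", "re_scale", "egger_intercept",
                    "egger_intercept_p"):
            if key in self.extras:
                lines.append(f"  {key} = {self.extras[key]:.4g}")
        return "\n".join(lines)


def results_frame(estimates) -> pd.DataFrame:
    """Tidy table with one row per estimate."""
    return pd.DataFrame([e.to_row() for e in estimates])


@dataclass
class RatioSet:
    """Per-SNP Wald ratios with first-order SEs and IVW weights."""

    ratios: np.ndarray
    ratio_se: np.ndarray

    def __post_init__(self):
        self.ratios = np.asarray(self.ratios, float).ravel()
        self.ratio_se = np.asarray(self.ratio_se, float).ravel()
        if self.ratios.shape != self.ratio_se.shape:
            raise ValidationError("ratio/ratio_se length mismatch")
        if (self.ratio_se <= 0).any():
            raise ValidationError("ratio_se must be positive")

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.ratio_se**2


def ratio_set(h: HarmonizedSet) -> RatioSet:
    _require_single(h)
    bx, by = h.exposure_beta(), h.beta_outcome
    if (bx == 0).any():
        raise UndefinedRatioError("zero exposure beta: Wald ratio undefined")
    return RatioSet(by / bx, h.se_outcome / np.abs(bx))


def _require_single(h: HarmonizedSet):
    if h.n_exposures != 1:
        raise ValidationError(
            "univariable estimator called with multiple exposures; use mvmr.mv_ivw"
        )


def _require_k(h: HarmonizedSet, k_min: int, method: str):
    if h.k < k_min:
        hint = " (use wald_ratio for a single SNP)" if k_min == 2 else ""
        raise InsufficientInstrumentsError(
            f"{method} needs at least {k_min} instruments, got {h.k}{hint}"
        )


def wald_ratio(beta_x, se_x, beta_y, se_y, *, binary=False,
               exposure=None, outcome=None) -> MREstimate:
    """Single-SNP causal estimate beta_y/beta_x with first-order SE."""
    if beta_x == 0:
        raise UndefinedRatioError("beta_x = 0: Wald ratio undefined")
    beta = beta_y / beta_x
    se = se_y / abs(beta_x)
    return MREstimate.from_normal(
        "wald_ratio", beta, se, 1, binary=binary, exposure=exposure, outcome=outcome
    )


def ivw(h: HarmonizedSet, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate (weighted LS through the origin).

    With ``random_effects`` (the default, matching the main-analysis
    convention) the SE is the fixed-effects SE scaled by
    max(1, sqrt(Q/(k-1))) — a multiplicative random-effects model that never
    shrinks the SE below fixed effects.
    """
    _require_single(h)
    _require_k(h, 2, "ivw")
    bx, by = h.exposure_beta(), h.beta_outcome
    w = 1.0 / h.se_outcome**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    q_df = h.k - 1
    scale = max(1.0, np.sqrt(q / q_df)) if random_effects else 1.0
    return MREstimate.from_normal(
        "ivw_re" if random_effects else "ivw_fe",
        beta,
        se_fixed * scale,
        h.k,
        binary=h.outcome_binary,
        exposure=h.exposure_names[0],
        outcome=h.outcome_name,
        extras={
            "cochran_q": q,
            "q_df": q_df,
            "q_pvalue": float(stats.chi2.sf(q, q_df)),
            "re_scale": float(scale),
        },
    )


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted LS of beta_Y on beta_X with intercept.

    Rows with negative exposure betas are flipped (both betas negated) so the
    intercept is identified; the slope is the causal estimate, the intercept
    the average directional pleiotropy.  SEs use the multiplicative
    random-effects scale max(1, sqrt(RSS_w/(k-2))).
    """
    _require_single(h)
    _require_k(h, 3, "egger")
    bx, by = h.exposure_beta().copy(), h.beta_outcome.copy()
    flip = bx < 0
    bx[flip] = -bx[flip]
    by[flip] = -by[flip]
    w = 1.0 / h.se_outcome**2
    sw = np.sqrt(w)
    X = np.column_stack([np.ones_like(bx), bx])
    coef, *_ = np.linalg.lstsq(X * sw[:, None], by * sw, rcond=None)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss_w / (h.k - 2)))
    cov_unscaled = np.linalg.inv(X.T @ (X * w[:, None]))
    se_int = float(np.sqrt(cov_unscaled[0, 0])) * scale
    se_slope = float(np.sqrt(cov_unscaled[1, 1])) * scale
    intercept, slope = float(coef[0]), float(coef[1])
    return MREstimate.from_normal(
        "egger",
        slope,
        se_slope,
        h.k,
        binary=h.outcome_binary,
        exposure=h.exposure_names[0],
        outcome=h.outcome_name,
        extras={
            "egger_intercept": intercept,
            "egger_intercept_se": se_int,
            "egger_intercept_p": _pvalue(intercept, se_int),
            "re_scale": float(scale),
            "flipped_variants": [v for v, f in zip(h.variant_ids, flip) if f],
        },
    )


def median_point(ratios, weights) -> float:
    """Weighted-median point estimate by cumulative-midpoint interpolation.

    Sort the ratios; with normalized weights w'_j the cumulative midpoint of
    ratio j is p_j = sum_{i<=j} w'_i - w'_j/2; the estimate interpolates the
    sorted ratios linearly at p = 0.5.
    """
    ratios = np.asarray(ratios, float)
    weights = np.asarray(weights, float)
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, cum, r))


def mode_point(ratios, weights, bandwidth_factor: float = 1.0) -> float:
    """Weighted-mode point estimate: argmax of a weighted normal-kernel KDE.

    Bandwidth is ``bandwidth_factor`` times the weighted-MAD default
    0.9 * 1.4826 * MAD_w * k^(-1/5).  A zero bandwidth (all ratios equal, up
    to weighted MAD 0) returns the weighted median exactly.
    """
    ratios = np.asarray(ratios, float)
    weights = np.asarray(weights, float)
    wm = median_point(ratios, weights)
    mad = median_point(np.abs(ratios - wm), weights)
    bw = bandwidth_factor * 0.9 * 1.4826 * mad * len(ratios) ** (-0.2)
    if bw <= 0:
        return wm
    wn = weights / weights.sum()

    def neg_density(x):
        return -np.sum(wn * np.exp(-0.5 * ((x - ratios) / bw) ** 2), axis=-1)

    grid = np.linspace(ratios.min() - 3 * bw, ratios.max() + 3 * bw, 2048)
    dens = np.sum(
        wn * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / bw) ** 2), axis=1
    )
    i = int(np.argmax(dens))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_density, bounds=(lo, hi), method="bounded")
    return float(res.x)


def _bootstrap_draws(h: HarmonizedSet, n_boot: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Parametric bootstrap: resample betas from normals with their SEs."""
    rng = np.random.default_rng(seed)
    bx = rng.normal(h.exposure_beta(), h.exposure_se(), size=(n_boot, h.k))
    by = rng.normal(h.beta_outcome, h.se_outcome, size=(n_boot, h.k))
    bx = np.where(bx == 0, np.finfo(float).eps, bx)
    ratios = by / bx
    weights = bx**2 / h.se_outcome**2
    return ratios, weights


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed=None) -> MREstimate:
    """Weighted-median estimator; SE from a seeded parametric bootstrap."""
    _require_single(h)
    _require_k(h, 3, "weighted_median")
    r = ratio_set(h)
    beta = median_point(r.ratios, r.weights)
    ratios_b, weights_b = _bootstrap_draws(h, n_boot, seed)
    order = np.argsort(ratios_b, axis=1)
    rs = np.take_along_axis(ratios_b, order, axis=1)
    ws = np.take_along_axis(weights_b, order, axis=1)
    ws = ws / ws.sum(axis=1, keepdims=True)
    cum = np.cumsum(ws, axis=1) - ws / 2.0
    draws = np.array([np.interp(0.5, cum[i], rs[i]) for i in range(n_boot)])
    se = float(draws.std(ddof=1))
    return MREstimate.from_normal(
        "weighted_median", beta, se, h.k,
        binary=h.outcome_binary, exposure=h.exposure_names[0],
        outcome=h.outcome_name, extras={"n_boot": n_boot},
    )


def weighted_mode(h: HarmonizedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed=None) -> MREstimate:
    """Weighted-mode estimator; SE from a seeded parametric bootstrap."""
    _require_single(h)
    _require_k(h, 3, "weighted_mode")
    r = ratio_set(h)
    beta = mode_point(r.ratios, r.weights, bandwidth_factor)
    ratios_b, weights_b = _bootstrap_draws(h, n_boot, seed)
    draws = np.array([
        mode_point(ratios_b[i], weights_b[i], bandwidth_factor)
        for i in range(n_boot)
    ])
    se = float(draws.std(ddof=1))
    return MREstimate.from_normal(
        "weighted_mode", beta, se, h.k,
        binary=h.outcome_binary, exposure=h.exposure_names[0],
        outcome=h.outcome_name,
        extras={"n_boot": n_boot, "bandwidth_factor": bandwidth_factor},
    )


@dataclass
class InstrumentStrength:
    """Per-variant F statistics and the weak-instrument flags (F < 10)."""

    variant_ids: list[str]
    f_stats: np.ndarray
    mean_f: float
    weak: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variant_id": self.variant_ids,
            "f_stat": self.f_stats,
            "weak": [v in set(self.weak) for v in self.variant_ids],
        })


def instrument_strength(h: HarmonizedSet, threshold: float = 10.0,
                        exposure: int = 0) -> InstrumentStrength:
    """Per-variant F = (beta_X/se_X)^2; variants below ``threshold`` flagged."""
    f = (h.exposure_beta(exposure) / h.exposure_se(exposure)) ** 2
    weak = [v for v, fi in zip(h.variant_ids, f) if fi < threshold]
    return InstrumentStrength(list(h.variant_ids), f, float(f.mean()), weak)


class UnivariableMR:
    """Univariable two-sample MR model for a single exposure-outcome pair.

    Parameters
    ----------
    harmonized : HarmonizedSet
        Must contain exactly one exposure.
    seed : int, optional
        Seed for the bootstrap SEs of the median/mode estimators.

    Examples
    --------
    >>> model = UnivariableMR(harmonized, seed=7)
    >>> res = model.fit()              # random-effects IVW
    >>> res = model.fit("egger")
    >>> table = model.fit_all()        # tidy frame across methods
    """

    _METHODS = ("ivw", "ivw_fe", "egger", "weighted_median", "weighted_mode")

    def __init__(self, harmonized: HarmonizedSet, seed=None):
        _require_single(harmonized)
        self.harmonized = harmonized
        self.seed = seed

    def fit(self, method: str = "ivw", **kwargs) -> MREstimate:
        h = self.harmonized
        if method == "ivw":
            return ivw(h, random_effects=kwargs.pop("random_effects", True))
        if method == "ivw_fe":
            return ivw(h, random_effects=False)
        if method == "egger":
            return egger(h)
        if method == "weighted_median":
            kwargs.setdefault("seed", self.seed)
            return weighted_median(h, **kwargs)
        if method == "weighted_mode":
            kwargs.setdefault("seed", self.seed)
            return weighted_mode(h, **kwargs)
        raise ValueError(f"unknown method {method!r}; choose from {self._METHODS}")

    def fit_all(self, methods=("ivw", "egger", "weighted_median", "weighted_mode"),
                **kwargs) -> pd.DataFrame:
        ests = []
        for m in methods:
            try:
                ests.append(self.fit(m, **dict(kwargs)))
            except InsufficientInstrumentsError:
                continue
        return results_frame(ests)

    def instrument_strength(self, threshold: float = 10.0) -> InstrumentStrength:
        return instrument_strength(self.harmonized, threshold)
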