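"""Multivariable MR: direct effects of several exposures with mutual adjustment.

MV-IVW regresses the per-SNP outcome associations on the k x m matrix of
exposure associations with no intercept, weights 1/se_Y^2.  Each coefficient
is an exposure's direct effect holding the other exposures fixed.  SEs use the
multiplicative random-effects scale max(1, sqrt(RSS_w/(k-m))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import MREstimate, results_frame
from .exceptions import CollinearityError, InsufficientInstrumentsError
from .summary_data import HarmonizedSet, SummaryStats, LDMatrix, harmonize, select_instruments

__all__ = ["mv_ivw", "conditional_f", "MultivariableMR", "MVMRResults", "pool_instruments"]


def _check_rank(X: np.ndarray, names) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        offending = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if others.shape[1] == 0:
                continue
            coef, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            resid = X[:, j] - others @ coef
            denom = float(np.sum(X[:, j] ** 2)) or 1.0
            if float(np.sum(resid**2)) / denom < 1e-10:
                offending.append(names[j])
        raise CollinearityError(
            f"exposure beta matrix is rank deficient (collinear exposures: {offending})",
            exposures=offending,
        )


def conditional_f(h: HarmonizedSet) -> dict:
    """Approximate conditional F per exposure (diagnostic only).

    Each exposure's betas are regressed on the other exposures' betas; the
    conditional F is the mean squared residual t-statistic, measuring the
    instrument strength left after adjustment.
    """
    X = h.beta_exposures
    out = {}
    for j, name in enumerate(h.exposure_names):
        others = np.delete(X, j, axis=1)
        if others.shape[1]:
            coef, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            resid = X[:, j] - others @ coef
        else:
            resid = X[:, j]
        out[name] = float(np.mean((resid / h.se_exposures[:, j]) ** 2))
    return out


def mv_ivw(h: HarmonizedSet) -> list[MREstimate]:
    """Multivariable IVW: one direct-effect estimate per exposure.

    Requires k > m instruments and a full-column-rank exposure matrix.  With a
    single exposure this reduces exactly to univariable IVW on the same rows.
    """
    k, m = h.k, h.n_exposures
    if k <= m:
        raise InsufficientInstrumentsError(
            f"mv_ivw needs more instruments than exposures (k={k}, m={m})"
        )
    X, y = h.beta_exposures, h.beta_outcome
    w = 1.0 / h.se_outcome**2
    sw = np.sqrt(w)
    # an all-zero column is a null exposure, not a collinearity problem: it
    # gets coefficient 0 with infinite SE and is excluded from the fit
    zero_cols = np.all(X == 0, axis=0)
    Xf = X[:, ~zero_cols]
    names_f = [n for n, z in zip(h.exposure_names, zero_cols) if not z]
    _check_rank(Xf * sw[:, None], names_f)
    coef_f, *_ = np.linalg.lstsq(Xf * sw[:, None], y * sw, rcond=None)
    coef = np.zeros(m)
    coef[~zero_cols] = coef_f
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(rss_w / (k - m))) if k > m else 1.0
    cov_f = np.linalg.inv(Xf.T @ (Xf * w[:, None])) * scale**2
    cov = np.full((m, m), np.inf)
    cov[np.ix_(~zero_cols, ~zero_cols)] = cov_f
    cond_f = conditional_f(h)
    estimates = []
    for j, name in enumerate(h.exposure_names):
        adjusted = [e for e in h.exposure_names if e != name]
        estimates.append(
            MREstimate.from_normal(
                "mv_ivw",
                coef[j],
                np.sqrt(cov[j, j]),
                k,
                binary=h.outcome_binary,
                exposure=name,
                outcome=h.outcome_name,
                extras={
                    "re_scale": float(scale),
                    "conditional_f": cond_f[name],
                    "adjusted_for": "+".join(adjusted) if adjusted else "",
                },
            )
        )
    return estimates


def pool_instruments(
    traits: list[SummaryStats],
    p_threshold: float = 5e-8,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    reclump: bool = True,
) -> list[str]:
    """Union-then-intersect instrument pooling for MVMR.

    Take the union of each trait's clumped genome-wide-significant variants,
    keep those present in every trait's summary set, and (by default) re-clump
    the pooled list against the first trait's p-values.
    """
    union: list[str] = []
    seen = set()
    for t in traits:
        for v in select_instruments(t, p_threshold, ld, r2_threshold, window_kb):
            if v not in seen:
                union.append(v)
                seen.add(v)
    shared = set(traits[0].variant_ids)
    for t in traits[1:]:
        shared &= set(t.variant_ids)
    pooled = [v for v in union if v in shared]
    if reclump and pooled:
        ref = traits[0].subset(pooled)
        pooled = select_instruments(ref, p_threshold=1.1, ld=ld,
                                    r2_threshold=r2_threshold, window_kb=window_kb)
    return pooled


@dataclass
class MVMRResults:
    """Results of a multivariable MR fit: one estimate per exposure."""

    estimates: list[MREstimate]
    conditional_f: dict

    def __getitem__(self, key):
        if isinstance(key, str):
            for e in self.estimates:
                if e.exposure == key:
                    return e
            raise KeyError(key)
        return self.estimates[key]

    def to_frame(self) -> pd.DataFrame:
        return results_frame(self.estimates)

    def summary(self) -> str:
        lines = [f"Multivariable IVW ({self.estimates[0].n_snps} instruments, "
                 f"outcome {self.estimates[0].outcome})"]
        for e in self.estimates:
            lines.append(
                f"  {e.exposure:<20s} beta {e.beta:+.4f} (se {e.se:.4f}) "
                f"p {e.pvalue:.3g}  cond. F {e.extras['conditional_f']:.1f}"
            )
        return "\n".join(lines)


class MultivariableMR:
    """Multivariable MR model over a HarmonizedSet with m >= 1 exposures.

    ``fit()`` returns :class:`MVMRResults`.  Can also be built directly from
    summary statistics with :meth:`from_summary_stats`, which pools
    instruments across the exposures and harmonizes.
    """

    def __init__(self, harmonized: HarmonizedSet):
        self.harmonized = harmonized

    @classmethod
    def from_summary_stats(cls, exposures, outcome, ld=None, p_threshold=5e-8,
                           r2_threshold=0.001, window_kb=10_000,
                           palindromic_eaf_limit=0.42):
        pooled = pool_instruments(list(exposures), p_threshold, ld,
                                  r2_threshold, window_kb)
        subs = [e.subset(pooled) for e in exposures]
        h = harmonize(subs, outcome, palindromic_eaf_limit)
        return cls(h)

    def fit(self) -> MVMRResults:
        ests = mv_ivw(self.harmonized)
        return MVMRResults(ests, conditional_f(self.harmonized))
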