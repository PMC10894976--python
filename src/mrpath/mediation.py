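"""Two-step mediation MR and the four-criterion mediator screen.

Two-step mediation MR estimates the indirect (mediated) effect of an exposure
on an outcome as the product of

* beta1 — the exposure -> mediator effect (univariable IVW), and
* beta2 — the mediator -> outcome direct effect adjusted for the exposure
  (multivariable IVW),

and the mediated proportion as beta1*beta2 divided by the total exposure ->
outcome effect.  The proportion's standard error comes from the first-order
delta method, var(beta1*beta2) = beta1^2 se2^2 + beta2^2 se1^2, treating the
two steps as independent (two-sample setting) and, by default, the total
effect as fixed; set ``propagate_total=True`` to add the full ratio-delta term
for the total effect's uncertainty.

A candidate mediator passes the screen when (1) the exposure causally affects
the mediator but not vice versa (forward UVMR significant, reverse UVMR null,
Steiger direction correct), (2) the mediator affects the outcome in UVMR,
(3) the mediator's MVMR effect on the outcome adjusted for the exposure is
significant, and (4) the mediated path's sign matches the total effect's sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import ivw
from .exceptions import (
    EmptyInputError,
    InsufficientInstrumentsError,
    UndefinedProportionError,
    UndefinedRatioError,
)
from .mvmr import mv_ivw
from .robustness import steiger_filter, steiger_test
from .summary_data import SummaryStats, harmonize, select_instruments

__all__ = [
    "MediationResult",
    "ScreenReport",
    "two_step_mediation",
    "screen_mediators",
    "mediation_table",
    "MediationMR",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MediationResult:
    """Indirect effect and mediated proportion with delta-method CI."""

    exposure: str
    mediator: str
    outcome: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    total_effect: float
    se_total: float
    indirect: float
    proportion: float
    proportion_se: float
    proportion_ci: tuple
    out_of_range: bool = False

    def summary(self) -> str:
        lo, hi = self.proportion_ci
        flag = "  [|proportion| > 1: possible inconsistent mediation]" if self.out_of_range else ""
        return (
            f"Mediation {self.exposure} -> {self.mediator} -> {self.outcome}\n"
            f"  beta1 = {self.beta1:+.4f} (se {self.se1:.4f})\n"
            f"  beta2 = {self.beta2:+.4f} (se {self.se2:.4f})\n"
            f"  total = {self.total_effect:+.4f}, indirect = {self.indirect:+.4f}\n"
            f"  mediated proportion = {100 * self.proportion:.1f}% "
            f"(95% CI {100 * lo:.1f}% to {100 * hi:.1f}%){flag}"
        )

    def to_row(self) -> dict:
        lo, hi = self.proportion_ci
        return {
            "exposure": self.exposure,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "beta1": self.beta1,
            "se1": self.se1,
            "beta2": self.beta2,
            "se2": self.se2,
            "total_effect": self.total_effect,
            "indirect": self.indirect,
            "proportion": self.proportion,
            "proportion_se": self.proportion_se,
            "proportion_ci_low": lo,
            "proportion_ci_high": hi,
            "proportion_pct": 100 * self.proportion,
            "proportion_pct_ci": f"{100 * lo:.1f} to {100 * hi:.1f}",
            "out_of_range": self.out_of_range,
        }


def two_step_mediation(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    total_effect: float,
    se_total: float = 0.0,
    *,
    propagate_total: bool = False,
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
) -> MediationResult:
    """Mediated proportion beta1*beta2/total with a delta-method 95% CI.

    With ``propagate_total=False`` (default) the total effect is treated as
    fixed and proportion_se = sqrt(beta1^2 se2^2 + beta2^2 se1^2)/|total|;
    with ``propagate_total=True`` the ratio-delta term
    indirect^2 se_total^2 / total^4 is added.
    """
    if total_effect == 0:
        raise UndefinedProportionError("total effect is zero: proportion undefined")
    indirect = beta1 * beta2
    var_indirect = beta1**2 * se2**2 + beta2**2 * se1**2
    proportion = indirect / total_effect
    var_prop = var_indirect / total_effect**2
    if propagate_total:
        var_prop += indirect**2 * se_total**2 / total_effect**4
    se_prop = float(np.sqrt(var_prop))
    ci = (proportion - _Z95 * se_prop, proportion + _Z95 * se_prop)
    out_of_range = abs(proportion) > 1
    if out_of_range:
        warnings.warn(
            f"mediated proportion {proportion:.2f} outside [-1, 1]: "
            "possible inconsistent mediation",
            stacklevel=2,
        )
    return MediationResult(
        exposure=exposure, mediator=mediator, outcome=outcome,
        beta1=float(beta1), se1=float(se1), beta2=float(beta2), se2=float(se2),
        total_effect=float(total_effect), se_total=float(se_total),
        indirect=float(indirect), proportion=float(proportion),
        proportion_se=se_prop, proportion_ci=(float(ci[0]), float(ci[1])),
        out_of_range=out_of_range,
    )


@dataclass
class ScreenReport:
    """Outcome of the four-criterion mediator screen for one pair.

    Criteria are True/False, or None when they could not be evaluated
    (e.g. no instruments for a required direction); ``eligible`` requires all
    four to be True.
    """

    mediator: str
    outcome: str
    criterion1: bool | None = None  # exposure -> mediator, no reverse causation
    criterion2: bool | None = None  # mediator -> outcome (UVMR)
    criterion3: bool | None = None  # mediator -> outcome adjusted for exposure
    criterion4: bool | None = None  # mediated path sign matches total effect
    stats: dict = field(default_factory=dict)
    reasons: list = field(default_factory=list)

    @property
    def eligible(self) -> bool:
        return all(c is True for c in
                   (self.criterion1, self.criterion2, self.criterion3, self.criterion4))

    def to_row(self) -> dict:
        row = {
            "mediator": self.mediator,
            "outcome": self.outcome,
            "criterion1": self.criterion1,
            "criterion2": self.criterion2,
            "criterion3": self.criterion3,
            "criterion4": self.criterion4,
            "eligible": self.eligible,
            "reasons": ";".join(self.reasons),
        }
        row.update(self.stats)
        return row


def screen_mediators(
    exposure: SummaryStats,
    mediators,
    outcome: SummaryStats,
    alpha: float = 0.05,
    *,
    ld=None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    palindromic_eaf_limit: float = 0.42,
) -> list[ScreenReport]:
    """Apply the four-criterion mediator screen to each candidate.

    ``ld`` may be a single LDMatrix (used for every trait) or a mapping of
    trait name -> LDMatrix.  Missing instruments for a required direction mark
    that criterion indeterminate (None) and the candidate ineligible.
    """

    def _ld_for(trait):
        if ld is None or hasattr(ld, "r2_between"):
            return ld
        return ld.get(trait.trait_name)

    def _select(trait):
        return select_instruments(trait, p_threshold, _ld_for(trait),
                                  r2_threshold, window_kb)

    exp_iv = _select(exposure)
    reports = []
    for med in mediators:
        rep = ScreenReport(mediator=med.trait_name, outcome=outcome.trait_name)
        med_iv = _select(med)
        beta1 = None

        # criterion 1: forward causal, no reverse causation, Steiger-consistent
        try:
            h_fwd = harmonize([exposure.subset(exp_iv)], med, palindromic_eaf_limit)
            fwd = ivw(h_fwd)
            st = steiger_test(h_fwd, exposure.median_n(), med.median_n())
            h_rev = harmonize([med.subset(med_iv)], exposure, palindromic_eaf_limit)
            # purge exposure-driven SNPs from the mediator's instrument set
            # before the reverse test (per-SNP Steiger direction filter);
            # with a genetically correlated mediator they would otherwise
            # manufacture a spurious reverse association
            keep = steiger_filter(h_rev, med.median_n(), exposure.median_n())
            if keep.sum() >= 2:
                h_rev = h_rev.subset(keep)
            rev = ivw(h_rev)
            beta1 = fwd.beta
            rep.stats.update(forward_p=fwd.pvalue, reverse_p=rev.pvalue,
                             beta1=fwd.beta, se1=fwd.se,
                             steiger_direction=st.direction_correct)
            rep.criterion1 = bool(
                fwd.pvalue < alpha and rev.pvalue >= alpha and st.direction_correct
            )
        except (InsufficientInstrumentsError, EmptyInputError, UndefinedRatioError) as exc:
            rep.reasons.append(f"criterion1: {exc}")

        # criterion 2: mediator -> outcome in UVMR
        try:
            h_mo = harmonize([med.subset(med_iv)], outcome, palindromic_eaf_limit)
            uv = ivw(h_mo)
            rep.stats.update(uvmr_med_outcome_p=uv.pvalue, uvmr_med_outcome_beta=uv.beta)
            rep.criterion2 = bool(uv.pvalue < alpha)
        except (InsufficientInstrumentsError, EmptyInputError, UndefinedRatioError) as exc:
            rep.reasons.append(f"criterion2: {exc}")

        # criterion 3: mediator -> outcome adjusted for the exposure (MVMR)
        beta2 = None
        try:
            pooled = []
            seen = set()
            for v in med_iv + exp_iv:
                if v not in seen:
                    pooled.append(v)
                    seen.add(v)
            h_mv = harmonize(
                [med.subset(pooled), exposure.subset(pooled)],
                outcome, palindromic_eaf_limit,
            )
            mv = mv_ivw(h_mv)
            med_est = next(e for e in mv if e.exposure == med.trait_name)
            beta2 = med_est.beta
            rep.stats.update(mvmr_med_outcome_p=med_est.pvalue, beta2=med_est.beta,
                             se2=med_est.se)
            rep.criterion3 = bool(med_est.pvalue < alpha)
        except (InsufficientInstrumentsError, EmptyInputError, UndefinedRatioError) as exc:
            rep.reasons.append(f"criterion3: {exc}")

        # criterion 4: mediated path sign must match the total effect's sign
        try:
            h_xo = harmonize([exposure.subset(exp_iv)], outcome, palindromic_eaf_limit)
            total = ivw(h_xo)
            rep.stats.update(total_effect=total.beta, total_se=total.se,
                             total_p=total.pvalue)
            if beta1 is not None and beta2 is not None:
                rep.criterion4 = bool(np.sign(beta1 * beta2) == np.sign(total.beta))
            else:
                rep.reasons.append("criterion4: beta1/beta2 unavailable")
        except (InsufficientInstrumentsError, EmptyInputError, UndefinedRatioError) as exc:
            rep.reasons.append(f"criterion4: {exc}")

        reports.append(rep)
    return reports


def mediation_table(results) -> pd.DataFrame:
    """Tidy mediation table: one row per (mediator, outcome).

    Proportions are reported as percentages with their CIs; rows sort by
    outcome then descending proportion.
    """
    columns = [
        "exposure", "mediator", "outcome", "beta1", "se1", "beta2", "se2",
        "total_effect", "indirect", "proportion", "proportion_se",
        "proportion_ci_low", "proportion_ci_high", "proportion_pct",
        "proportion_pct_ci", "out_of_range",
    ]
    if not results:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame([r.to_row() for r in results])
    return df.sort_values(
        ["outcome", "proportion"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)[columns]


class MediationMR:
    """Two-step mediation MR model built from summary statistics.

    Screens the candidate mediators, then for each eligible one estimates
    beta1 (UVMR exposure -> mediator), beta2 (MVMR mediator -> outcome
    adjusted for the exposure) and the total effect, and combines them with
    :func:`two_step_mediation`.
    """

    def __init__(self, exposure, mediators, outcome, alpha=0.05, *, ld=None,
                 p_threshold=5e-8, r2_threshold=0.001, window_kb=10_000,
                 palindromic_eaf_limit=0.42, propagate_total=False):
        self.exposure = exposure
        self.mediators = list(mediators)
        self.outcome = outcome
        self.alpha = alpha
        self.ld = ld
        self.p_threshold = p_threshold
        self.r2_threshold = r2_threshold
        self.window_kb = window_kb
        self.palindromic_eaf_limit = palindromic_eaf_limit
        self.propagate_total = propagate_total

    def screen(self) -> list[ScreenReport]:
        return screen_mediators(
            self.exposure, self.mediators, self.outcome, self.alpha,
            ld=self.ld, p_threshold=self.p_threshold,
            r2_threshold=self.r2_threshold, window_kb=self.window_kb,
            palindromic_eaf_limit=self.palindromic_eaf_limit,
        )

    def fit(self, screen_first: bool = True):
        """Return (list of MediationResult, list of ScreenReport)."""
        reports = self.screen()
        by_name = {m.trait_name: m for m in self.mediators}
        results = []
        for rep in reports:
            if screen_first and not rep.eligible:
                continue
            needed = ("beta1", "beta2", "se2", "total_effect")
            if not all(k in rep.stats for k in needed):
                continue
            med = by_name[rep.mediator]
            # se1 from the forward UVMR, recomputed to carry its SE
            exp_iv = select_instruments(self.exposure, self.p_threshold,
                                        self.ld if (self.ld is None or hasattr(self.ld, "r2_between"))
                                        else self.ld.get(self.exposure.trait_name),
                                        self.r2_threshold, self.window_kb)
            h_fwd = harmonize([self.exposure.subset(exp_iv)], med,
                              self.palindromic_eaf_limit)
            fwd = ivw(h_fwd)
            h_xo = harmonize([self.exposure.subset(exp_iv)], self.outcome,
                             self.palindromic_eaf_limit)
            total = ivw(h_xo)
            results.append(
                two_step_mediation(
                    fwd.beta, fwd.se, rep.stats["beta2"], rep.stats["se2"],
                    total.beta, total.se, propagate_total=self.propagate_total,
                    exposure=self.exposure.trait_name, mediator=rep.mediator,
                    outcome=self.outcome.trait_name,
                )
            )
        return results, reports
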