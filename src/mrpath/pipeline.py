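"""Config-driven three-step study pipeline.

Step 1 runs bidirectional UVMR among the exposures; step 2 runs UVMR of every
exposure on every outcome source with the sensitivity suite, pools estimates
across sources per disease by fixed-effects meta-analysis, applies
Benjamini-Hochberg FDR within each exposure's disease family
(significant: FDR p < 0.05; suggestive: nominal p < 0.05 but FDR p >= 0.05),
and runs MVMR of all exposures jointly per disease; step 3 screens the
candidate mediators and runs two-step mediation MR for the diseases carried
forward from step 2 (those where the primary exposure retains a nominal MVMR
association).

All outputs are tidy TSVs plus a JSON run manifest; with a fixed config and
seed the outputs are bit-identical across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import __version__
from .estimators import UnivariableMR, ivw, results_frame
from .exceptions import (
    ConfigurationError,
    EmptyInputError,
    InsufficientInstrumentsError,
    MRError,
    ValidationError,
)
from .mediation import mediation_table, screen_mediators, two_step_mediation
from .mvmr import mv_ivw
from .robustness import mr_presso
from .summary_data import harmonize, read_ld_matrix, read_summary_stats, select_instruments

__all__ = [
    "bh_fdr",
    "meta_fixed",
    "MetaResult",
    "label_association",
    "AssociationLabel",
    "TraitSpec",
    "StudyConfig",
    "run_study",
    "StudyReport",
]

logger = logging.getLogger("mrpath")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValidationError("bh_fdr needs at least one p-value")
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class MetaResult:
    """Fixed-effects inverse-variance pooled estimate."""

    beta: float
    se: float
    pvalue: float
    q: float
    q_df: int
    q_pvalue: float
    n_sources: int


def meta_fixed(estimates) -> MetaResult:
    """Fixed-effects meta-analysis of independent (beta, se) pairs."""
    arr = [(float(b), float(s)) for b, s in estimates]
    if not arr:
        raise EmptyInputError("meta_fixed needs at least one estimate")
    betas = np.array([b for b, _ in arr])
    ses = np.array([s for _, s in arr])
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (betas - beta) ** 2))
    q_df = max(len(arr) - 1, 0)
    q_p = float(stats.chi2.sf(q, q_df)) if q_df else 1.0
    p = max(float(2.0 * stats.norm.sf(abs(beta / se))), np.finfo(float).tiny)
    return MetaResult(beta, se, p, q, q_df, q_p, len(arr))


@dataclass(frozen=True)
class AssociationLabel:
    """Trichotomous label from nominal and FDR-adjusted p-values.

    significant: FDR p < 0.05; suggestive: nominal p < 0.05 with FDR p >= 0.05;
    null otherwise.
    """

    nominal_p: float
    fdr_p: float

    @property
    def label(self) -> str:
        if self.fdr_p < 0.05:
            return "significant"
        if self.nominal_p < 0.05:
            return "suggestive"
        return "null"


def label_association(nominal_p: float, fdr_p: float) -> str:
    return AssociationLabel(nominal_p, fdr_p).label


@dataclass
class TraitSpec:
    """One trait's file location and metadata inside a study config."""

    name: str
    path: str
    trait_type: str = "continuous"
    column_map: dict = field(default_factory=dict)
    disease: str | None = None  # outcomes: sources sharing a disease are pooled
    source: str | None = None

    def load(self, base: Path):
        p = Path(self.path)
        if not p.is_absolute():
            p = base / p
        return read_summary_stats(p, self.column_map or None,
                                  trait_name=self.name, trait_type=self.trait_type)


@dataclass
class StudyConfig:
    """Full parameterization of a study run (thresholds, traits, seeds)."""

    exposures: list
    outcomes: list
    mediators: list = field(default_factory=list)
    ld: str | None = None
    primary_exposure: str | None = None
    p_instrument: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000
    alpha: float = 0.05
    fdr_q: float = 0.05
    palindromic_eaf_limit: float = 0.42
    n_sim_presso: int = 1000
    bootstrap_draws: int = 1000
    seed: int = 0
    output_dir: str = "mrpath_results"
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path} is not a mapping")
        for key in ("exposures", "outcomes"):
            if key not in raw:
                raise ConfigurationError(f"config missing required key {key!r}")

        def specs(items):
            return [TraitSpec(**it) for it in items]

        kwargs = {k: v for k, v in raw.items()
                  if k not in ("exposures", "outcomes", "mediators")}
        cfg = cls(
            exposures=specs(raw["exposures"]),
            outcomes=specs(raw["outcomes"]),
            mediators=specs(raw.get("mediators", [])),
            base_dir=path.parent,
            **kwargs,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ConfigurationError("need at least one exposure and one outcome")
        for spec in self.exposures + self.outcomes + self.mediators:
            p = Path(spec.path)
            if not p.is_absolute():
                p = self.base_dir / p
            if not p.exists():
                raise ConfigurationError(f"summary-statistics file not found: {p}")
        if self.primary_exposure is None:
            self.primary_exposure = self.exposures[0].name

    def to_dict(self) -> dict:
        def spec_dict(s):
            return {k: v for k, v in s.__dict__.items() if v not in (None, {}, [])}

        return {
            "exposures": [spec_dict(s) for s in self.exposures],
            "outcomes": [spec_dict(s) for s in self.outcomes],
            "mediators": [spec_dict(s) for s in self.mediators],
            "ld": self.ld,
            "primary_exposure": self.primary_exposure,
            "p_instrument": self.p_instrument,
            "clump_r2": self.clump_r2,
            "clump_window_kb": self.clump_window_kb,
            "alpha": self.alpha,
            "fdr_q": self.fdr_q,
            "palindromic_eaf_limit": self.palindromic_eaf_limit,
            "n_sim_presso": self.n_sim_presso,
            "bootstrap_draws": self.bootstrap_draws,
            "seed": self.seed,
        }


@dataclass
class StudyReport:
    """Frames produced by :func:`run_study` plus the paths written."""

    frames: dict
    paths: dict
    failures: list

    def summary(self) -> str:
        lines = ["Study run complete"]
        for name, df in self.frames.items():
            lines.append(f"  {name}: {len(df)} rows -> {self.paths.get(name, '-')}")
        if self.failures:
            lines.append(f"  failures: {len(self.failures)} (see run log)")
        return "\n".join(lines)


def _task_seed(base_seed: int, counter: int) -> int:
    return int((base_seed * 1_000_003 + 7919 * (counter + 1)) % (2**31 - 1))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def run_study(config: StudyConfig, out_dir=None) -> StudyReport:
    """Execute the three-step study and write tidy TSVs plus a manifest.

    Stage failures (too few instruments, empty intersections, ...) are logged
    and isolated; the affected cell is marked failed rather than aborting.
    """
    config.validate()
    out = Path(out_dir) if out_dir is not None else Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failures: list[str] = []
    log_lines = [f"mrpath {__version__}", f"seed {config.seed}"]

    ld = read_ld_matrix(
        Path(config.ld) if Path(config.ld).is_absolute() else config.base_dir / config.ld
    ) if config.ld else None

    exposures = {s.name: s.load(config.base_dir) for s in config.exposures}
    mediators = {s.name: s.load(config.base_dir) for s in config.mediators}
    sources = [(s.disease or s.name, s.source or "source1", s.load(config.base_dir))
               for s in config.outcomes]
    diseases = list(dict.fromkeys(d for d, _, _ in sources))
    primary = config.primary_exposure

    def clump(trait):
        return select_instruments(trait, config.p_instrument, ld,
                                  config.clump_r2, config.clump_window_kb)

    iv = {name: clump(t) for name, t in {**exposures, **mediators}.items()}
    for name, lst in iv.items():
        log_lines.append(f"instruments[{name}] = {len(lst)}")

    task = 0

    # ---- step 1: bidirectional UVMR among exposures -----------------------
    step1_rows = []
    for a in exposures.values():
        for b in exposures.values():
            if a.trait_name == b.trait_name:
                continue
            try:
                h = harmonize([a.subset(iv[a.trait_name])], b,
                              config.palindromic_eaf_limit)
                step1_rows.append(ivw(h).to_row())
            except MRError as exc:
                failures.append(f"step1 {a.trait_name}->{b.trait_name}: {exc}")
    step1 = pd.DataFrame(step1_rows)

    # ---- step 2: UVMR per exposure x outcome source + sensitivity ---------
    uvmr_rows, presso_rows = [], []
    ivw_by_cell: dict = {}
    for exp_name, exp in exposures.items():
        for disease, source, out_stats in sources:
            task += 1
            try:
                h = harmonize([exp.subset(iv[exp_name])], out_stats,
                              config.palindromic_eaf_limit)
                model = UnivariableMR(h, seed=_task_seed(config.seed, task))
                for m in ("ivw", "egger", "weighted_median", "weighted_mode"):
                    try:
                        kw = {"n_boot": config.bootstrap_draws} \
                            if m in ("weighted_median", "weighted_mode") else {}
                        est = model.fit(m, **kw)
                        row = est.to_row()
                        row.update(disease=disease, source=source)
                        uvmr_rows.append(row)
                        if m == "ivw":
                            ivw_by_cell[(exp_name, disease, source)] = est
                    except InsufficientInstrumentsError as exc:
                        failures.append(f"step2 {exp_name}x{source} {m}: {exc}")
                try:
                    pr = mr_presso(h, config.n_sim_presso, config.alpha,
                                   seed=_task_seed(config.seed, task))
                    presso_rows.append({
                        "exposure": exp_name, "disease": disease, "source": source,
                        "global_rss": pr.global_rss, "global_p": pr.global_p,
                        "n_outliers": len(pr.outliers),
                        "outliers": ";".join(pr.outliers),
                        "beta_raw": pr.beta_raw, "beta_corrected": pr.beta_corrected,
                        "distortion_p": pr.distortion_p,
                    })
                except (InsufficientInstrumentsError, MRError) as exc:
                    failures.append(f"step2 presso {exp_name}x{source}: {exc}")
            except MRError as exc:
                failures.append(f"step2 {exp_name}x{disease}/{source}: {exc}")
    step2_uvmr = pd.DataFrame(uvmr_rows)
    step2_presso = pd.DataFrame(presso_rows)

    # meta-analysis across sources per disease, then FDR per exposure family
    meta_rows = []
    for exp_name in exposures:
        for disease in diseases:
            cells = [ivw_by_cell[(exp_name, d, s)]
                     for d, s, _ in sources
                     if d == disease and (exp_name, d, s) in ivw_by_cell]
            if not cells:
                failures.append(f"meta {exp_name}x{disease}: no estimates")
                continue
            mr = meta_fixed([(e.beta, e.se) for e in cells])
            meta_rows.append({
                "exposure": exp_name, "disease": disease,
                "beta": mr.beta, "se": mr.se, "pvalue": mr.pvalue,
                "odds_ratio": float(np.exp(mr.beta)),
                "or_ci_low": float(np.exp(mr.beta - 1.959963984540054 * mr.se)),
                "or_ci_high": float(np.exp(mr.beta + 1.959963984540054 * mr.se)),
                "q": mr.q, "q_pvalue": mr.q_pvalue, "n_sources": mr.n_sources,
            })
    step2_meta = pd.DataFrame(meta_rows)
    if not step2_meta.empty:
        step2_meta["fdr_p"] = np.nan
        for exp_name, grp in step2_meta.groupby("exposure"):
            step2_meta.loc[grp.index, "fdr_p"] = bh_fdr(grp["pvalue"].to_numpy())
        step2_meta["label"] = [
            label_association(r.pvalue, r.fdr_p) for r in step2_meta.itertuples()
        ]

    # MVMR: all exposures jointly, per disease (first source is primary)
    mvmr_rows = []
    primary_mvmr_p: dict = {}
    pooled_ids = list(dict.fromkeys(
        v for name in exposures for v in iv[name]
    ))
    primary_source = {d: next(s for dd, s, _ in sources if dd == d) for d in diseases}
    stats_by_src = {(d, s): st for d, s, st in sources}
    for disease in diseases:
        src = primary_source[disease]
        try:
            h = harmonize(
                [e.subset(pooled_ids) for e in exposures.values()],
                stats_by_src[(disease, src)], config.palindromic_eaf_limit,
            )
            for est in mv_ivw(h):
                row = est.to_row()
                row.update(disease=disease, source=src)
                mvmr_rows.append(row)
                if est.exposure == primary:
                    primary_mvmr_p[disease] = est.pvalue
        except MRError as exc:
            failures.append(f"mvmr {disease}: {exc}")
    step2_mvmr = pd.DataFrame(mvmr_rows)

    # carry forward: primary exposure keeps a nominal direct effect
    carried = [d for d in diseases if primary_mvmr_p.get(d, 1.0) < config.alpha]
    tiers = {}
    if not step2_meta.empty:
        for d in carried:
            sel = step2_meta[(step2_meta["exposure"] == primary)
                             & (step2_meta["disease"] == d)]
            tiers[d] = sel["label"].iloc[0] if len(sel) else "unknown"
    log_lines.append(f"carried_forward = {carried} tiers = {tiers}")

    # ---- step 3: mediator screen + two-step mediation ----------------------
    screen_rows, mediation_results = [], []
    exp_primary = exposures[primary]
    total_by_disease = {}
    if not step2_meta.empty:
        for r in step2_meta.itertuples():
            if r.exposure == primary:
                total_by_disease[r.disease] = (r.beta, r.se)
    for disease in carried:
        out_stats = stats_by_src[(disease, primary_source[disease])]
        try:
            reports = screen_mediators(
                exp_primary, list(mediators.values()), out_stats,
                config.alpha, ld=ld, p_threshold=config.p_instrument,
                r2_threshold=config.clump_r2, window_kb=config.clump_window_kb,
                palindromic_eaf_limit=config.palindromic_eaf_limit,
            )
        except MRError as exc:
            failures.append(f"step3 screen {disease}: {exc}")
            continue
        for rep in reports:
            row = rep.to_row()
            row["disease"] = disease
            row["tier"] = tiers.get(disease, "unknown")
            screen_rows.append(row)
            if not rep.eligible:
                continue
            total_beta, total_se = total_by_disease.get(
                disease, (rep.stats.get("total_effect"), rep.stats.get("total_se")))
            try:
                mediation_results.append(two_step_mediation(
                    rep.stats["beta1"], rep.stats["se1"],
                    rep.stats["beta2"], rep.stats["se2"],
                    total_beta, total_se,
                    exposure=primary, mediator=rep.mediator, outcome=disease,
                ))
            except MRError as exc:
                failures.append(f"step3 mediation {rep.mediator}x{disease}: {exc}")
    step3_screen = pd.DataFrame(screen_rows)
    step3_mediation = mediation_table(mediation_results)

    frames = {
        "step1_bidirectional": step1,
        "step2_uvmr": step2_uvmr,
        "step2_presso": step2_presso,
        "step2_meta": step2_meta,
        "step2_mvmr": step2_mvmr,
        "step3_screen": step3_screen,
        "step3_mediation": step3_mediation,
    }
    paths = {}
    for name, df in frames.items():
        path = out / f"{name}.tsv"
        _write_tsv(df, path)
        paths[name] = str(path)

    manifest = {
        "package": "mrpath",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "carried_forward": carried,
        "tiers": tiers,
        "n_failures": len(failures),
        "outputs": {k: Path(v).name for k, v in paths.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = str(out / "manifest.json")
    log_lines += [f"FAIL {f}" for f in failures]
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info(line)

    return StudyReport(frames=frames, paths=paths, failures=failures)
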