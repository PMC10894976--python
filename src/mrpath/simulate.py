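"""Synthetic multi-trait GWAS summary statistics under a known causal model.

The generator emulates the structural model behind a two-step mediation MR
study::

    exposure --beta1--> mediator --beta2--> outcome
        \\_________________direct_effect________/

Per-SNP effects on the exposure are gamma_j ~ N(0, gamma_sd^2) for the
exposure-instrument block; a second block of mediator-specific instruments
carries delta_j ~ N(0, delta_sd^2) on the mediator (and nothing on the
exposure), which is what makes the mediator -> outcome MVMR step identifiable.
True per-SNP effects are then

    mediator_j = beta1 * gamma_j + delta_j
    outcome_j  = (direct_effect + beta1*beta2) * gamma_j + beta2 * delta_j + alpha_j

with alpha_j the horizontal-pleiotropy term (none / balanced / directional,
applied to the outcome).  Observed betas add noise with the standard GWAS
standard error se_j = 1/sqrt(2 n maf_j (1-maf_j)) for a unit-variance trait;
binary outcomes are generated directly on the log-odds scale with the same
formula inflated by 1/sqrt(cf (1-cf)) for case fraction cf — an approximation
adequate for method testing, not a case-control likelihood simulation.

Instruments are mutually independent (identity LD) by default; an optional
equal-r2 block mode exists solely to exercise clumping.  Effect alleles are
always the minor allele at generation time (downstream harmonization tests
permute and flip alleles to exercise that path).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .summary_data import HarmonizedSet, LDMatrix, SummaryStats

__all__ = [
    "Pleiotropy",
    "ScenarioConfig",
    "ScenarioTruth",
    "ScenarioData",
    "simulate_summary_stats",
    "scenario_library",
    "simulate_study",
    "write_study",
]

_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass(frozen=True)
class Pleiotropy:
    """Horizontal-pleiotropy specification for the outcome trait.

    kind: "none", "balanced" (zero-mean) or "directional" (nonzero mean).
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "balanced", "directional"):
            raise ValidationError(f"unknown pleiotropy kind {self.kind!r}")
        if self.sd < 0:
            raise ValidationError("pleiotropy sd must be >= 0")
        if self.kind == "balanced" and self.mean != 0:
            raise ValidationError("balanced pleiotropy has zero mean")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one synthetic scenario.

    Defaults are the partial-mediation study conditions: effect sizes echoing
    an education -> smoking -> gastric-ulcer-scale pathway (beta1 = -0.28,
    beta2 = 0.62, direct = -0.31, total = -0.4836, proportion ~ 0.359), an
    exposure GWAS of 766,345 (the education GWAS scale), a large mediator GWAS
    and a 200k case-control outcome GWAS on the log-odds scale.
    """

    n_snps: int = 150
    n_snps_mediator: int = 100
    maf_range: tuple = (0.05, 0.5)
    gamma_sd: float = 0.035
    delta_sd: float = 0.05
    beta1: float = -0.28
    beta2: float = 0.62
    direct_effect: float = -0.31
    pleiotropy: Pleiotropy = field(default_factory=lambda: Pleiotropy("balanced", sd=0.01))
    n_exposure: int = 766_345
    n_mediator: int = 600_000
    n_outcome: int = 200_000
    outcome_type: str = "binary"
    case_fraction: float = 0.1
    outlier_index: int | None = None
    outlier_effect: float = 0.0
    reverse_causation: bool = False
    reverse_effect: float = 0.3
    ld_block_size: int | None = None
    ld_block_r2: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        for name in ("gamma_sd", "delta_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) < 100:
                raise ValidationError(f"{name} must be >= 100")
        if self.outcome_type not in ("continuous", "binary"):
            raise ValidationError(f"unknown outcome_type {self.outcome_type!r}")
        if self.outcome_type == "binary" and not (0 < self.case_fraction < 1):
            raise ValidationError("case_fraction must be in (0, 1)")
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")


@dataclass
class ScenarioTruth:
    """Generating truth of a scenario; the algebraic identities hold exactly."""

    total_effect: float
    mediation_proportion: float
    beta1: float
    beta2: float
    direct_effect: float
    gamma: np.ndarray  # true per-SNP effects on the exposure
    delta: np.ndarray  # mediator-specific per-SNP effects
    alpha: np.ndarray  # pleiotropic per-SNP effects on the outcome
    exposure_instruments: list
    mediator_instruments: list
    outlier_id: str | None = None


@dataclass
class ScenarioData:
    """Simulated summary statistics plus LD and the generating truth.

    Iterable as the 5-tuple (exposure, mediator, outcome, ld, truth).
    """

    exposure: SummaryStats
    mediator: SummaryStats
    outcome: SummaryStats
    ld: LDMatrix
    truth: ScenarioTruth
    config: ScenarioConfig

    def __iter__(self):
        return iter((self.exposure, self.mediator, self.outcome, self.ld, self.truth))

    def harmonized(self, outcome: str = "outcome",
                   exposures=("exposure",), instruments: str = "exposure") -> HarmonizedSet:
        """Fast aligned HarmonizedSet straight from the generator's tables.

        The generator emits every trait on the same (minor) effect allele, so
        no allele logic is needed; this is a convenience for Monte-Carlo
        loops.  ``instruments`` selects the SNP block: "exposure",
        "mediator", or "all".
        """
        by_name = {"exposure": self.exposure, "mediator": self.mediator,
                   "outcome": self.outcome}
        ids = {
            "exposure": self.truth.exposure_instruments,
            "mediator": self.truth.mediator_instruments,
            "all": self.truth.exposure_instruments + self.truth.mediator_instruments,
        }[instruments]
        idx = {v: i for i, v in enumerate(self.exposure.variant_ids)}
        rows = np.array([idx[v] for v in ids], dtype=int)
        out = by_name[outcome]
        exps = [by_name[e] for e in exposures]
        return HarmonizedSet(
            variant_ids=ids,
            beta_exposures=np.column_stack(
                [e.data["beta"].to_numpy(float)[rows] for e in exps]),
            se_exposures=np.column_stack(
                [e.data["se"].to_numpy(float)[rows] for e in exps]),
            beta_outcome=out.data["beta"].to_numpy(float)[rows],
            se_outcome=out.data["se"].to_numpy(float)[rows],
            exposure_names=[e.trait_name for e in exps],
            outcome_name=out.trait_name,
            outcome_binary=out.trait_type == "binary",
        )


def _snp_layout(k: int, block: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous per-chromosome chunks, 1 Mb between neighbours.

    When a block size is given the chunks are rounded up to whole blocks so
    an LD block never straddles a chromosome boundary.
    """
    chunk = -(-k // 22)  # ceil
    if block:
        chunk = -(-chunk // block) * block
    chrom = np.array([str(j // chunk + 1) for j in range(k)])
    pos = np.array([1_000_000 * (j % chunk + 1) for j in range(k)], dtype=np.int64)
    return chrom, pos


def _gwas_se(n, maf, case_fraction=None):
    se = 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))
    if case_fraction is not None:
        se = se / np.sqrt(case_fraction * (1.0 - case_fraction))
    return se


def _observe(name, trait_type, true_beta, se, ids, chrom, pos, ea, oa, maf, n, rng):
    beta_hat = true_beta + rng.normal(0.0, se)
    z = beta_hat / se
    pvalue = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    df = pd.DataFrame({
        "variant_id": ids, "chromosome": chrom, "position": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": maf,
        "beta": beta_hat, "se": se, "pvalue": pvalue,
        "n": np.full(len(ids), n, dtype=np.int64),
    })
    return SummaryStats(name, trait_type, df)


def simulate_summary_stats(config: ScenarioConfig) -> ScenarioData:
    """Simulate exposure/mediator/outcome summary statistics for a scenario.

    Returns a :class:`ScenarioData`, iterable as the 5-tuple
    (exposure, mediator, outcome, ld, truth).  All draws come from a single
    generator seeded by ``config.seed``: the same seed reproduces every table
    bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    k_exp, k_med = config.n_snps, config.n_snps_mediator
    k = k_exp + k_med

    ids = [f"rs{j + 1:06d}" for j in range(k)]
    chrom, pos = _snp_layout(k, config.ld_block_size)
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=k)
    ea = np.array([_NONPALINDROMIC_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_NONPALINDROMIC_PAIRS[i][1] for i in pair_idx])
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=k)

    gamma = np.zeros(k)
    delta = np.zeros(k)
    gamma[:k_exp] = rng.normal(0.0, config.gamma_sd, size=k_exp)
    if k_med:
        delta[k_exp:] = rng.normal(0.0, config.delta_sd, size=k_med)

    if config.pleiotropy.kind == "none":
        alpha = np.zeros(k)
    else:
        alpha = rng.normal(config.pleiotropy.mean, config.pleiotropy.sd, size=k)
        if config.pleiotropy.kind == "directional":
            # directional pleiotropy acts relative to the exposure-increasing
            # allele; orient it with gamma so it survives the Egger flip
            alpha = alpha * np.where(gamma >= 0, 1.0, -1.0)

    outlier_id = None
    if config.outlier_index is not None:
        alpha = alpha.copy()
        alpha[config.outlier_index] += config.outlier_effect
        outlier_id = ids[config.outlier_index]

    total = config.direct_effect + config.beta1 * config.beta2
    if config.reverse_causation:
        # gamma are instruments of the *outcome*; the exposure inherits
        # reverse_effect * gamma and nothing flows exposure -> outcome.
        true_exp = config.reverse_effect * gamma
        true_med = np.zeros(k)
        true_out = gamma + alpha
        truth_total = 0.0
    else:
        true_exp = gamma
        true_med = config.beta1 * gamma + delta
        true_out = total * gamma + config.beta2 * delta + alpha
        truth_total = total

    se_exp = _gwas_se(config.n_exposure, maf)
    se_med = _gwas_se(config.n_mediator, maf)
    cf = config.case_fraction if config.outcome_type == "binary" else None
    se_out = _gwas_se(config.n_outcome, maf, cf)

    exposure = _observe("exposure", "continuous", true_exp, se_exp,
                        ids, chrom, pos, ea, oa, maf, config.n_exposure, rng)
    mediator = _observe("mediator", "continuous", true_med, se_med,
                        ids, chrom, pos, ea, oa, maf, config.n_mediator, rng)
    outcome = _observe("outcome", config.outcome_type, true_out, se_out,
                       ids, chrom, pos, ea, oa, maf, config.n_outcome, rng)

    if config.ld_block_size:
        r2 = np.eye(k)
        for start in range(0, k, config.ld_block_size):
            stop = min(start + config.ld_block_size, k)
            r2[start:stop, start:stop] = config.ld_block_r2
            np.fill_diagonal(r2[start:stop, start:stop], 1.0)
        ld = LDMatrix(ids, r2)
    else:
        ld = LDMatrix.identity(ids)

    truth = ScenarioTruth(
        total_effect=truth_total,
        mediation_proportion=(config.beta1 * config.beta2 / total) if total != 0 else np.nan,
        beta1=config.beta1,
        beta2=config.beta2,
        direct_effect=config.direct_effect,
        gamma=gamma,
        delta=delta,
        alpha=alpha,
        exposure_instruments=ids[:k_exp],
        mediator_instruments=ids[k_exp:],
        outlier_id=outlier_id,
    )
    return ScenarioData(exposure, mediator, outcome, ld, truth, config)


def scenario_library() -> dict:
    """Named scenarios covering the behaviours each diagnostic must detect.

    Every scenario ships with seed 0; use ``dataclasses.replace(cfg, seed=s)``
    to rerun under a different seed.
    """
    base = ScenarioConfig()
    return {
        # no causal effect anywhere; balanced pleiotropy only
        "null": replace(base, n_snps=100, n_snps_mediator=0,
                        beta1=0.0, beta2=0.0, direct_effect=0.0,
                        pleiotropy=Pleiotropy("balanced", sd=0.01)),
        # exposure affects the outcome only directly; mediator on-path is dead
        "total-effect-only": replace(base, beta2=0.0, direct_effect=-0.48),
        # the entire effect flows through the mediator
        "full-mediation": replace(base, direct_effect=0.0),
        # ~35.9% mediated, the scale of the smoking-initiation/gastric-ulcer path
        "partial-mediation": base,
        # directional pleiotropy an Egger intercept should flag
        "directional-pleiotropy": replace(
            base, pleiotropy=Pleiotropy("directional", mean=0.01, sd=0.01)),
        # one planted outlier among otherwise clean instruments (PRESSO bait)
        "single-outlier": replace(
            base, n_snps=21, n_snps_mediator=0, beta1=0.0, beta2=0.0,
            direct_effect=-0.31, pleiotropy=Pleiotropy("none"),
            outlier_index=0, outlier_effect=0.1),
        # outcome causes the exposure; Steiger should refuse the forward model
        "reverse-causation": replace(
            base, n_snps_mediator=0, beta1=0.0, beta2=0.0, direct_effect=0.0,
            pleiotropy=Pleiotropy("none"), reverse_causation=True,
            reverse_effect=0.3, outcome_type="continuous"),
    }


# ---------------------------------------------------------------------------
# Study-level synthetic dataset: three correlated exposures, two candidate
# mediators, three diseases (one with two sources) — enough structure for the
# full three-step pipeline to have something true to find.
# ---------------------------------------------------------------------------

def simulate_study(seed: int = 0, n_snps_exposure: int = 40,
                   n_snps_secondary: int = 30, n_snps_mediator: int = 30):
    """Simulate the multi-trait summary statistics for a whole study.

    Structure: ``education`` is the primary exposure with its own instrument
    block; ``intelligence`` and ``cognition`` load on education's genetic
    effects (0.6 and 0.5) plus their own blocks, giving the bidirectional
    step-1 pattern.  ``smoking`` is a true mediator (beta1 = -0.28 from
    education, beta2 = +0.62 into gastric ulcer); ``diet`` is affected by
    education but affects no disease.  ``gastric_ulcer`` (two sources,
    meta-analysed) carries a -0.31 direct effect plus the mediated path
    (total -0.4836, ~35.9% mediated); ``duodenal_ulcer`` is direct-only;
    ``ibs`` is null.  Returns (traits, sources, ld, truth_dict) where traits
    maps name -> SummaryStats and sources lists (disease, source,
    SummaryStats) for the outcome GWASs.
    """
    rng = np.random.default_rng(seed)
    blocks = {
        "edu": n_snps_exposure,
        "intel": n_snps_secondary,
        "cogn": n_snps_secondary,
        "smoking": n_snps_mediator,
        "diet": n_snps_mediator,
    }
    k = sum(blocks.values())
    ids = [f"rs{j + 1:06d}" for j in range(k)]
    chrom, pos = _snp_layout(k)
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=k)
    ea = np.array([_NONPALINDROMIC_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_NONPALINDROMIC_PAIRS[i][1] for i in pair_idx])
    maf = rng.uniform(0.05, 0.5, size=k)

    effects = {}
    start = 0
    for name, size in blocks.items():
        e = np.zeros(k)
        e[start:start + size] = rng.normal(0.0, 0.035 if name == "edu" else 0.05,
                                           size=size)
        effects[name] = e
        start += size

    beta1, beta2, direct = -0.28, 0.62, -0.31
    true = {
        "education": effects["edu"],
        "intelligence": 0.6 * effects["edu"] + effects["intel"],
        "cognition": 0.5 * effects["edu"] + effects["cogn"],
        "smoking": beta1 * effects["edu"] + effects["smoking"],
        "diet": -0.2 * effects["edu"] + effects["diet"],
    }
    true["gastric_ulcer"] = direct * true["education"] + beta2 * true["smoking"]
    true["duodenal_ulcer"] = -0.3 * true["education"]
    true["ibs"] = np.zeros(k)

    meta = {
        "education": ("continuous", 766_345, None),
        "intelligence": ("continuous", 269_867, None),
        "cognition": ("continuous", 257_841, None),
        "smoking": ("continuous", 600_000, None),
        "diet": ("continuous", 600_000, None),
    }
    out_meta = {
        ("gastric_ulcer", "finngen"): (150_000, 0.10),
        ("gastric_ulcer", "gera"): (60_000, 0.08),
        ("duodenal_ulcer", "finngen"): (150_000, 0.05),
        ("ibs", "finngen"): (150_000, 0.10),
    }

    traits = {}
    for name, (ttype, n, cf) in meta.items():
        se = _gwas_se(n, maf, cf)
        traits[name] = _observe(name, ttype, true[name], se,
                                ids, chrom, pos, ea, oa, maf, n, rng)
    sources = []
    for (disease, source), (n, cf) in out_meta.items():
        se = _gwas_se(n, maf, cf)
        pleio = rng.normal(0.0, 0.005, size=k)
        ss = _observe(f"{disease}_{source}", "binary", true[disease] + pleio, se,
                      ids, chrom, pos, ea, oa, maf, n, rng)
        sources.append((disease, source, ss))

    truth = {
        "beta1": beta1,
        "beta2": beta2,
        "direct_effect": direct,
        "total_effect": direct + beta1 * beta2,
        "mediation_proportion": beta1 * beta2 / (direct + beta1 * beta2),
        "true_mediator": "smoking",
        "causal_diseases": ["gastric_ulcer", "duodenal_ulcer"],
        "null_diseases": ["ibs"],
    }
    return traits, sources, LDMatrix.identity(ids), truth


def write_study(out_dir, seed: int = 0, n_sim_presso: int = 500,
                bootstrap_draws: int = 500, **kwargs) -> str:
    """Write a full synthetic study (TSVs, LD matrix, truth, YAML config).

    Returns the path of the written config file, ready for
    :func:`mrpath.pipeline.run_study` /  ``mrpath run``.
    """
    import json

    import yaml

    from .summary_data import write_ld_matrix

    out = __import__("pathlib").Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traits, sources, ld, truth = simulate_study(seed, **kwargs)

    exposure_names = ["education", "intelligence", "cognition"]
    mediator_names = ["smoking", "diet"]
    for name in exposure_names + mediator_names:
        traits[name].write_tsv(out / f"{name}.tsv")
    outcome_specs = []
    for disease, source, ss in sources:
        fname = f"{disease}_{source}.tsv"
        ss.write_tsv(out / fname)
        outcome_specs.append({"name": ss.trait_name, "path": fname,
                              "trait_type": "binary", "disease": disease,
                              "source": source})
    write_ld_matrix(ld, out / "ld.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)

    config = {
        "seed": seed,
        "primary_exposure": "education",
        "ld": "ld.tsv",
        "n_sim_presso": n_sim_presso,
        "bootstrap_draws": bootstrap_draws,
        "exposures": [{"name": n, "path": f"{n}.tsv", "trait_type": "continuous"}
                      for n in exposure_names],
        "mediators": [{"name": n, "path": f"{n}.tsv", "trait_type": "continuous"}
                      for n in mediator_names],
        "outcomes": outcome_specs,
    }
    cfg_path = out / "study_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return str(cfg_path)
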