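"""GWAS summary statistics: containers, I/O, allele harmonization, LD clumping.

The central objects are :class:`SummaryStats` (one trait's per-variant
association table), :class:`LDMatrix` (pairwise r-squared supplied as input,
never computed from genotypes), and :class:`HarmonizedSet` (a variant-aligned
effect matrix for one or more exposures against one outcome, ready for the MR
estimators).

Harmonization follows the standard two-sample MR convention: every trait's
effects are re-expressed relative to the first exposure's effect allele,
flipping signs for label-swapped alleles and resolving strand flips through
base complements.  Palindromic (A/T, C/G) variants are oriented by allele
frequency when both frequencies are clearly away from 0.5, and dropped as
ambiguous otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, EmptyInputError, ValidationError

__all__ = [
    "REQUIRED_FIELDS",
    "SummaryStats",
    "LDMatrix",
    "HarmonizedSet",
    "LoadReport",
    "read_summary_stats",
    "read_ld_matrix",
    "write_ld_matrix",
    "harmonize",
    "select_instruments",
]

#: canonical column names of a summary-statistics table, in storage order
REQUIRED_FIELDS = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_BASES = frozenset("ACGT")


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


@dataclass
class LoadReport:
    """Row accounting for one :func:`read_summary_stats` call."""

    n_read: int = 0
    n_valid: int = 0
    n_dropped: int = 0
    drop_reasons: dict = field(default_factory=dict)


@dataclass
class SummaryStats:
    """Per-variant GWAS associations for a single trait.

    Parameters
    ----------
    trait_name : str
    trait_type : {"continuous", "binary"}
        Binary traits carry betas on the log-odds scale.
    data : pandas.DataFrame
        Columns :data:`REQUIRED_FIELDS`; ``eaf`` may be NaN (allowed for
        non-palindromic variants), everything else must be finite.
    """

    trait_name: str
    trait_type: str
    data: pd.DataFrame
    load_report: LoadReport | None = None

    def __post_init__(self):
        if self.trait_type not in ("continuous", "binary"):
            raise ValidationError(f"unknown trait_type {self.trait_type!r}")
        df = self.data
        missing = [c for c in REQUIRED_FIELDS if c not in df.columns]
        if missing:
            raise ValidationError(f"summary stats missing columns: {missing}")
        if df["variant_id"].duplicated().any():
            dups = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
            raise ValidationError(f"duplicate variant ids: {dups[:5]}")
        if (df["se"] <= 0).any():
            raise ValidationError("se must be strictly positive")
        eaf = df["eaf"].to_numpy(float)
        ok = np.isnan(eaf) | ((eaf >= 0) & (eaf <= 1))
        if not ok.all():
            raise ValidationError("eaf outside [0, 1]")
        self._check_pvalues()
        self.data = df.reset_index(drop=True)

    def _check_pvalues(self):
        """Warn (not fail) when reported p disagrees with |beta/se| badly."""
        df = self.data
        z = np.abs(df["beta"].to_numpy(float) / df["se"].to_numpy(float))
        expected = 2.0 * stats.norm.sf(z)
        reported = df["pvalue"].to_numpy(float)
        with np.errstate(divide="ignore"):
            mask = (expected > 1e-300) & (reported > 1e-300)
            off = np.abs(np.log10(reported[mask]) - np.log10(expected[mask]))
        if mask.any() and (off > 2).any():
            warnings.warn(
                f"{self.trait_name}: {(off > 2).sum()} p-values differ from the "
                "normal approximation by more than 2 orders of magnitude",
                stacklevel=3,
            )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def variant_ids(self) -> list[str]:
        return self.data["variant_id"].tolist()

    def record(self, variant_id: str) -> pd.Series:
        sub = self.data.loc[self.data["variant_id"] == variant_id]
        if sub.empty:
            raise KeyError(variant_id)
        return sub.iloc[0]

    def subset(self, variant_ids) -> "SummaryStats":
        """Restrict to the given variants, preserving their order."""
        idx = self.data.set_index("variant_id")
        keep = [v for v in variant_ids if v in idx.index]
        df = idx.loc[keep].reset_index()[list(REQUIRED_FIELDS)]
        return SummaryStats(self.trait_name, self.trait_type, df)

    def median_n(self) -> int:
        return int(np.median(self.data["n"].to_numpy(float)))

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_summary_stats(
    path,
    column_map: dict | None = None,
    trait_name: str | None = None,
    trait_type: str = "continuous",
    delimiter: str | None = None,
) -> SummaryStats:
    """Read a delimited summary-statistics file into a :class:`SummaryStats`.

    ``column_map`` maps canonical field names (:data:`REQUIRED_FIELDS`) to the
    file's column headers, e.g. ``{"effect_allele": "A1"}``; unmapped fields
    are looked up under their canonical names.  The delimiter is inferred from
    the extension (``.csv`` -> comma, otherwise tab) unless given.  Rows with
    missing or non-finite beta/se, non-positive se, or a p-value outside
    (0, 1] are dropped and counted in ``load_report``.
    """
    path = str(path)
    if delimiter is None:
        delimiter = "," if path.endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=delimiter)
    column_map = dict(column_map or {})
    rename = {}
    for canonical in REQUIRED_FIELDS:
        src = column_map.get(canonical, canonical)
        if src not in raw.columns:
            if canonical == "eaf" and canonical not in column_map:
                raw["eaf"] = np.nan
                continue
            raise ConfigurationError(
                f"column {src!r} (for field {canonical!r}) not found in {path}"
            )
        rename[src] = canonical
    df = raw.rename(columns=rename)[list(REQUIRED_FIELDS)].copy()

    report = LoadReport(n_read=len(df))
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    def _drop(mask: pd.Series, reason: str):
        n = int(mask.sum())
        if n:
            report.drop_reasons[reason] = report.drop_reasons.get(reason, 0) + n
        return df.loc[~mask]

    df = _drop(~np.isfinite(df["beta"]) | ~np.isfinite(df["se"]), "nonfinite_beta_se")
    df = _drop(df["se"] <= 0, "nonpositive_se")
    df = _drop(~np.isfinite(df["pvalue"]) | (df["pvalue"] <= 0) | (df["pvalue"] > 1), "bad_pvalue")
    df = _drop(
        ~df["effect_allele"].isin(_VALID_BASES)
        | ~df["other_allele"].isin(_VALID_BASES)
        | (df["effect_allele"] == df["other_allele"]),
        "bad_alleles",
    )
    report.n_valid = len(df)
    report.n_dropped = report.n_read - report.n_valid
    if report.n_valid == 0:
        raise EmptyInputError(f"no valid rows in {path}")

    df["variant_id"] = df["variant_id"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str)
    df["position"] = df["position"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    name = trait_name if trait_name is not None else path.rsplit("/", 1)[-1].split(".")[0]
    return SummaryStats(name, trait_type, df.reset_index(drop=True), load_report=report)


@dataclass
class LDMatrix:
    """Squared-correlation matrix over a set of variants.

    Symmetric, unit diagonal, entries in [0, 1].  Variants absent from the
    matrix are treated as unlinked by :func:`select_instruments`.
    """

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.variant_ids = list(self.variant_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValidationError("LD matrix shape does not match variant ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValidationError("LD matrix diagonal must be 1")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise ValidationError("LD r2 values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @classmethod
    def identity(cls, variant_ids) -> "LDMatrix":
        ids = list(variant_ids)
        return cls(ids, np.eye(len(ids)))

    def r2_between(self, a: str, b: str) -> float | None:
        """r2 of two variants, or None when either is not covered."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])


def read_ld_matrix(path, delimiter: str = "\t") -> LDMatrix:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    return LDMatrix(list(df.columns), df.to_numpy(float))


def write_ld_matrix(ld: LDMatrix, path, delimiter: str = "\t") -> None:
    df = pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids)
    df.to_csv(path, sep=delimiter, float_format="%.10g")


@dataclass
class HarmonizedSet:
    """Variant-aligned effects of m exposure(s) and one outcome.

    All betas refer to the same effect allele per variant; rows of every
    array share the order of ``variant_ids``.  ``drop_log`` records each
    variant removed during harmonization with exactly one reason.
    """

    variant_ids: list[str]
    beta_exposures: np.ndarray  # (k, m)
    se_exposures: np.ndarray  # (k, m)
    beta_outcome: np.ndarray  # (k,)
    se_outcome: np.ndarray  # (k,)
    exposure_names: list[str]
    outcome_name: str
    drop_log: list = field(default_factory=list)
    outcome_binary: bool = False

    def __post_init__(self):
        self.variant_ids = list(self.variant_ids)
        self.beta_exposures = np.atleast_2d(np.asarray(self.beta_exposures, float))
        self.se_exposures = np.atleast_2d(np.asarray(self.se_exposures, float))
        if self.beta_exposures.shape[0] == 1 and len(self.variant_ids) != 1:
            self.beta_exposures = self.beta_exposures.T
            self.se_exposures = self.se_exposures.T
        self.beta_outcome = np.asarray(self.beta_outcome, float).ravel()
        self.se_outcome = np.asarray(self.se_outcome, float).ravel()
        k = len(self.variant_ids)
        if self.beta_exposures.shape != self.se_exposures.shape:
            raise ValidationError("exposure beta/se shapes differ")
        if self.beta_exposures.shape[0] != k or len(self.beta_outcome) != k or len(self.se_outcome) != k:
            raise ValidationError("harmonized arrays do not share the variant dimension")
        if (self.se_exposures <= 0).any() or (self.se_outcome <= 0).any():
            raise ValidationError("standard errors must be positive")
        self.exposure_names = list(self.exposure_names)
        if len(self.exposure_names) != self.beta_exposures.shape[1]:
            raise ValidationError("exposure_names length does not match matrix")

    @property
    def k(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return self.beta_exposures.shape[1]

    def exposure_beta(self, j: int = 0) -> np.ndarray:
        return self.beta_exposures[:, j]

    def exposure_se(self, j: int = 0) -> np.ndarray:
        return self.se_exposures[:, j]

    def subset(self, keep) -> "HarmonizedSet":
        """New set restricted to a boolean mask or list of variant ids."""
        if isinstance(keep, (list, tuple, set)):
            mask = np.array([v in set(keep) for v in self.variant_ids])
        else:
            mask = np.asarray(keep, bool)
        ids = [v for v, m in zip(self.variant_ids, mask) if m]
        return replace(
            self,
            variant_ids=ids,
            beta_exposures=self.beta_exposures[mask],
            se_exposures=self.se_exposures[mask],
            beta_outcome=self.beta_outcome[mask],
            se_outcome=self.se_outcome[mask],
            drop_log=list(self.drop_log),
        )

    def to_frame(self) -> pd.DataFrame:
        out = {"variant_id": self.variant_ids}
        for j, name in enumerate(self.exposure_names):
            out[f"beta_{name}"] = self.beta_exposures[:, j]
            out[f"se_{name}"] = self.se_exposures[:, j]
        out[f"beta_{self.outcome_name}"] = self.beta_outcome
        out[f"se_{self.outcome_name}"] = self.se_outcome
        return pd.DataFrame(out)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")

    def write_drop_log(self, path) -> None:
        pd.DataFrame(self.drop_log, columns=["variant_id", "reason"]).to_csv(
            path, sep="\t", index=False
        )


def _align_to_reference(ref_ea, ref_oa, ea, oa):
    """Return +1/-1 sign to align (ea, oa) onto (ref_ea, ref_oa), or None.

    Handles label swaps and strand flips.  For palindromic reference alleles
    the +1 branch always matches; frequency-based orientation is applied by
    the caller.
    """
    if (ea, oa) == (ref_ea, ref_oa):
        return 1
    if (ea, oa) == (ref_oa, ref_ea):
        return -1
    cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)
    if (cea, coa) == (ref_ea, ref_oa):
        return 1
    if (cea, coa) == (ref_oa, ref_ea):
        return -1
    return None


def harmonize(
    exposures,
    outcome: SummaryStats,
    palindromic_eaf_limit: float = 0.42,
) -> HarmonizedSet:
    """Align one or more exposures and an outcome onto shared effect alleles.

    The first exposure defines the reference orientation.  For every variant
    in the intersection of all traits, each other trait is aligned by allele
    label (sign flip + eaf complement under a swap) or strand complement.
    Palindromic variants are kept only when every trait's minor-allele
    frequency is below ``palindromic_eaf_limit`` and the frequencies agree in
    orientation after label alignment; otherwise they are dropped with reason
    ``"palindromic_ambiguous"``.  Irreconcilable alleles drop the variant with
    reason ``"allele_mismatch"``.
    """
    if isinstance(exposures, SummaryStats):
        exposures = [exposures]
    exposures = list(exposures)
    if not exposures:
        raise EmptyInputError("no exposures supplied")
    traits = exposures + [outcome]

    indexed = [t.data.set_index("variant_id") for t in traits]
    shared = set(indexed[0].index)
    for idx in indexed[1:]:
        shared &= set(idx.index)
    if not shared:
        raise EmptyInputError("no shared variants between exposures and outcome")
    shared = sorted(shared)

    m = len(exposures)
    kept_ids, drop_log = [], []
    bx_rows, sx_rows, by_vals, sy_vals = [], [], [], []

    for vid in shared:
        ref = indexed[0].loc[vid]
        ref_ea, ref_oa = ref["effect_allele"], ref["other_allele"]
        palindromic = _is_palindromic(ref_ea, ref_oa)
        ref_eaf = float(ref["eaf"])
        if palindromic and (
            np.isnan(ref_eaf) or min(ref_eaf, 1 - ref_eaf) >= palindromic_eaf_limit
        ):
            drop_log.append((vid, "palindromic_ambiguous"))
            continue

        betas, ses = [float(ref["beta"])], [float(ref["se"])]
        reason = None
        for idx in indexed[1:]:
            rec = idx.loc[vid]
            sign = _align_to_reference(
                ref_ea, ref_oa, rec["effect_allele"], rec["other_allele"]
            )
            if sign is None:
                reason = "allele_mismatch"
                break
            eaf = float(rec["eaf"])
            aligned_eaf = eaf if sign == 1 else 1.0 - eaf
            if palindromic:
                if np.isnan(eaf) or min(eaf, 1 - eaf) >= palindromic_eaf_limit:
                    reason = "palindromic_ambiguous"
                    break
                # strand is unresolvable from labels: require frequency agreement
                if (ref_eaf < 0.5) != (aligned_eaf < 0.5):
                    reason = "palindromic_ambiguous"
                    break
            betas.append(sign * float(rec["beta"]))
            ses.append(float(rec["se"]))
        if reason is not None:
            drop_log.append((vid, reason))
            continue

        kept_ids.append(vid)
        bx_rows.append(betas[:m])
        sx_rows.append(ses[:m])
        by_vals.append(betas[m])
        sy_vals.append(ses[m])

    if not kept_ids:
        raise EmptyInputError("harmonization dropped every shared variant")

    return HarmonizedSet(
        variant_ids=kept_ids,
        beta_exposures=np.array(bx_rows, float),
        se_exposures=np.array(sx_rows, float),
        beta_outcome=np.array(by_vals, float),
        se_outcome=np.array(sy_vals, float),
        exposure_names=[e.trait_name for e in exposures],
        outcome_name=outcome.trait_name,
        drop_log=drop_log,
        outcome_binary=outcome.trait_type == "binary",
    )


def select_instruments(
    stats: SummaryStats,
    p_threshold: float = 5e-8,
    ld: LDMatrix | None = None,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> list[str]:
    """Greedy LD clumping of genome-wide significant variants.

    Variants with p < ``p_threshold`` are sorted by ascending p (ties broken
    by variant id); the best remaining variant becomes an index SNP and every
    remaining variant on the same chromosome within ``window_kb`` kb whose r2
    with it is >= ``r2_threshold`` is removed.  Variants not covered by ``ld``
    are treated as unlinked (with a warning).  Returns index SNPs in selection
    order.
    """
    df = stats.data.loc[stats.data["pvalue"] < p_threshold]
    if df.empty:
        return []
    df = df.sort_values(["pvalue", "variant_id"], kind="mergesort")

    if ld is not None:
        uncovered = [v for v in df["variant_id"] if v not in ld._index]
        if uncovered:
            warnings.warn(
                f"{len(uncovered)} significant variants absent from the LD matrix "
                "are treated as unlinked",
                stacklevel=2,
            )

    window_bp = float(window_kb) * 1000.0
    remaining = list(
        df[["variant_id", "chromosome", "position"]].itertuples(index=False, name=None)
    )
    selected = []
    while remaining:
        vid, chrom, pos = remaining.pop(0)
        selected.append(vid)
        survivors = []
        for ovid, ochrom, opos in remaining:
            if ochrom == chrom and abs(opos - pos) <= window_bp:
                r2 = ld.r2_between(vid, ovid) if ld is not None else None
                if r2 is not None and r2 >= r2_threshold:
                    continue  # clumped away
            survivors.append((ovid, ochrom, opos))
        remaining = survivors
    return selected
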