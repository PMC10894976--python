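import numpy as np
import pandas as pd
import pytest

from mrpath.summary_data import REQUIRED_FIELDS, HarmonizedSet, SummaryStats


def make_stats(rows, trait_name="trait", trait_type="continuous"):
    """Build a SummaryStats from a list of per-variant dicts with defaults."""
    defaults = {
        "chromosome": "1",
        "position": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.01,
        "pvalue": None,
        "n": 100_000,
    }
    recs = []
    for i, row in enumerate(rows):
        rec = dict(defaults, variant_id=f"rs{i + 1}", position=1000 + i)
        rec.update(row)
        from scipy import stats
        if rec["pvalue"] is None:
            rec["pvalue"] = max(
                2 * stats.norm.sf(abs(rec["beta"] / rec["se"])), 1e-300
            )
        elif "beta" not in row:
            # keep beta/se consistent with an explicitly requested p-value
            rec["beta"] = rec["se"] * stats.norm.isf(rec["pvalue"] / 2)
        recs.append(rec)
    df = pd.DataFrame(recs)[list(REQUIRED_FIELDS)]
    return SummaryStats(trait_name, trait_type, df)


def make_harmonized(bx, by, sx=None, sy=None, binary=False, names=None):
    """HarmonizedSet straight from arrays (already-aligned effects)."""
    bx = np.atleast_2d(np.asarray(bx, float))
    if bx.shape[0] == 1:
        bx = bx.T
    k, m = bx.shape
    sx = np.full_like(bx, 0.01) if sx is None else np.broadcast_to(
        np.asarray(sx, float).reshape(-1, 1) if np.ndim(sx) == 1 else sx, bx.shape
    ).copy()
    by = np.asarray(by, float)
    sy = np.full(k, 0.01) if sy is None else np.asarray(sy, float)
    if sy.ndim == 0:
        sy = np.full(k, float(sy))
    names = names or [f"exposure{j + 1}" for j in range(m)]
    return HarmonizedSet(
        variant_ids=[f"rs{i + 1}" for i in range(k)],
        beta_exposures=bx,
        se_exposures=sx,
        beta_outcome=by,
        se_outcome=sy,
        exposure_names=names,
        outcome_name="outcome",
        outcome_binary=binary,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def weighted_ls_oracle(X, y, w):
    """Independent weighted normal-equations solver: (X'WX) b = X'Wy."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1:
        X = X.T
    W = np.diag(np.asarray(w, float))
    A = X.T @ W @ X
    b = X.T @ W @ np.asarray(y, float)
    return np.linalg.solve(A, b)


def weighted_median_oracle(ratios, weights):
    """Brute-force cumulative-weight interpolation at p = 0.5."""
    pairs = sorted(zip(ratios, weights))
    r = [p[0] for p in pairs]
    w = [p[1] for p in pairs]
    total = sum(w)
    w = [wi / total for wi in w]
    cum = []
    running = 0.0
    for wi in w:
        cum.append(running + wi / 2.0)
        running += wi
    if 0.5 <= cum[0]:
        return r[0]
    if 0.5 >= cum[-1]:
        return r[-1]
    for i in range(1, len(r)):
        if cum[i - 1] <= 0.5 <= cum[i]:
            frac = (0.5 - cum[i - 1]) / (cum[i] - cum[i - 1])
            return r[i - 1] + frac * (r[i] - r[i - 1])
    raise AssertionError("unreachable")


def bh_oracle(pvalues):
    """Hand-coded Benjamini-Hochberg step-up adjustment."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [None] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * m / rank_from_top)
        adjusted[i] = val
        prev = val
    return adjusted
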