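"""Descriptive-panel aggregation and the concentration–aroma Spearman screen.

Trained assessors score each Baijiu sample's roasted-aroma intensity on a
0–7 scale in triplicate.  Per-sample panel means are then rank-correlated
with each compound's concentration across samples; compounds with a strong
positive monotone association (ρ above a cut, p below α) are flagged as
candidate drivers of the attribute.  The screen is directional — it looks
for *positive* relationships — so its default p-value is one-sided; the
flag rule is ρ > ``rho_min`` AND p < ``alpha``.

ρ is the Pearson correlation of mid-ranks (average ranks on ties).  For
n ≤ 9 common samples the p-value is an exact permutation tail over all n!
orderings; above that the usual t approximation
t = ρ·sqrt((n−2)/(1−ρ²)) on n−2 degrees of freedom is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateVarianceError, InsufficientDataError

#: Largest n for which the exact permutation p-value is enumerated.
EXACT_PERMUTATION_MAX_N = 9

RATING_COLUMNS = ("assessor", "replicate", "sample", "attribute", "score")


@dataclass(frozen=True)
class CorrelationResult:
    compound: str
    rho: float
    p_value: float
    significant: bool
    method: str  # "exact-permutation" | "t-approximation"
    degenerate: bool = False  # zero-variance column, rho undefined


def read_rating_table(path) -> pd.DataFrame:
    """Long-format panel ratings (assessor, replicate, sample, attribute, score)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = set(RATING_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"rating table missing columns: {sorted(missing)}")
    return validate_ratings(df)


def validate_ratings(df: pd.DataFrame) -> pd.DataFrame:
    if ((df["score"] < 0) | (df["score"] > 7)).any():
        raise DataError("scores must lie on the 0-7 scale")
    key = ["assessor", "replicate", "sample", "attribute"]
    if df.duplicated(subset=key).any():
        raise DataError("duplicate assessor x replicate x sample x attribute rows")
    return df


def aggregate_intensity(ratings: pd.DataFrame, attribute: str) -> pd.DataFrame:
    """Per-sample mean/sd/n of an attribute over assessors × replicates."""
    sub = ratings[ratings["attribute"] == attribute]
    if sub.empty:
        raise DataError(f"attribute {attribute!r} not present in rating table")
    prof = (
        sub.groupby("sample")["score"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .sort_index()
    )
    prof["sd"] = prof["sd"].fillna(0.0)
    return prof


def anova_by_sample(ratings: pd.DataFrame, attribute: str) -> tuple[float, float]:
    """One-way fixed-effect ANOVA of attribute scores across samples."""
    sub = ratings[ratings["attribute"] == attribute]
    if sub.empty:
        raise DataError(f"attribute {attribute!r} not present in rating table")
    groups = [grp["score"].to_numpy(dtype=float) for _, grp in sub.groupby("sample")]
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 samples")
    if any(len(g) < 2 for g in groups):
        raise InsufficientDataError("ANOVA needs >= 2 ratings per sample")
    if all(g.var(ddof=1) == 0 for g in groups):
        raise DegenerateVarianceError("zero within-group variance in every sample")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# Spearman screen


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rho(x, y) -> float:
    """Spearman ρ as the Pearson correlation of mid-ranks."""
    rx, ry = _midranks(np.asarray(x, float)), _midranks(np.asarray(y, float))
    if rx.std() == 0 or ry.std() == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, alternative: str) -> float:
    n = len(rx)
    rxc = rx - rx.mean()
    denom = math.sqrt((rxc**2).sum())
    perms = np.array(list(permutations(ry)), dtype=float)
    pc = perms - ry.mean()
    rhos = (pc @ rxc) / (denom * np.sqrt((pc**2).sum(axis=1)))
    rho_obs = float((ry - ry.mean()) @ rxc / (denom * math.sqrt(((ry - ry.mean()) ** 2).sum())))
    eps = 1e-12
    if alternative == "greater":
        return float(np.mean(rhos >= rho_obs - eps))
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - eps))


def spearman_pvalue(x, y, alternative: str = "greater") -> tuple[float, float, str]:
    """(ρ, p, method).  Exact permutation for n ≤ 9, t-approximation beyond."""
    if alternative not in {"greater", "two-sided"}:
        raise DataError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    rho = spearman_rho(x, y)
    if math.isnan(rho):
        return rho, float("nan"), "undefined"
    if n <= EXACT_PERMUTATION_MAX_N:
        return rho, _exact_permutation_p(_midranks(x), _midranks(y), alternative), "exact-permutation"
    if abs(rho) >= 1.0:
        # t statistic diverges; bound by the probability of a perfect ordering
        p = 1.0 / math.factorial(n)
        if alternative == "greater" and rho < 0:
            p = 1.0 - p
        return rho, p, "t-approximation"
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    if alternative == "greater":
        p = float(stats.t.sf(t, df=n - 2))
    else:
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, max(p, 1.0 / math.factorial(n))), "t-approximation"


def spearman_screen(
    concentrations: pd.DataFrame,
    profile: pd.DataFrame,
    rho_min: float = 0.5,
    alpha: float = 0.05,
    alternative: str = "greater",
    attribute: str = "roasted",
    fdr: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen every compound's concentrations against an intensity profile.

    Parameters
    ----------
    concentrations : wide table, index = compound, columns = samples.
    profile : per-sample table with a ``mean`` column (see aggregate_intensity),
        or any per-sample Series of intensities.
    rho_min, alpha : flag rule ρ > rho_min AND p < alpha.
    fdr : apply Benjamini–Hochberg to the p-values before flagging
        (off by default; no correction is the screen's standard behaviour).

    Returns (results, edges): one row per compound, and one weighted
    attribute–compound edge per significant compound.
    """
    intensity = profile["mean"] if isinstance(profile, pd.DataFrame) else profile
    common = [s for s in concentrations.columns if s in intensity.index]
    if len(common) < 4:
        raise InsufficientDataError(
            f"screen needs >= 4 common samples, got {len(common)}"
        )
    y = intensity.loc[common].to_numpy(dtype=float)
    rows = []
    for compound in concentrations.index:
        x = concentrations.loc[compound, common].to_numpy(dtype=float)
        rho, p, method = spearman_pvalue(x, y, alternative=alternative)
        rows.append(
            CorrelationResult(
                compound=compound,
                rho=rho,
                p_value=p,
                significant=False,
                method=method,
                degenerate=method == "undefined",
            )
        )
    res = pd.DataFrame([r.__dict__ for r in rows])
    p_for_flag = res["p_value"].copy()
    if fdr:
        ok = ~res["degenerate"]
        p_for_flag.loc[ok] = _benjamini_hochberg(res.loc[ok, "p_value"].to_numpy())
        res["p_adjusted"] = p_for_flag
    res["significant"] = (
        ~res["degenerate"] & (res["rho"] > rho_min) & (p_for_flag < alpha)
    )
    edges = res.loc[res["significant"], ["compound", "rho"]].copy()
    edges.insert(0, "attribute", attribute)
    edges = edges.rename(columns={"rho": "weight"}).reset_index(drop=True)
    return res, edges


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def write_screen(results: pd.DataFrame, edges: pd.DataFrame, results_tsv, edges_path) -> None:
    results.to_csv(results_tsv, sep="\t", index=False)
    edges.to_csv(edges_path, sep="\t", index=False)
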