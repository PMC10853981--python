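"""Clinical summaries and nonparametric statistics for the stroke cohort.

Implements, from first principles, the statistics used to link network
dynamics with upper-limb motor scores: median/IQR summaries (Tukey hinges),
minimal-clinically-important-difference (MCID) counts for ARAT and FM-UE,
recovery subgrouping, Mann-Whitney U and Wilcoxon signed-rank tests with
midrank tie handling and exact small-sample enumeration, 2 x 2 mixed-design
ANOVA with partial eta squared, Spearman (and first-order partial Spearman)
rank correlation, and Bonferroni correction.

Effect sizes follow the rank-test convention r = |Z| / sqrt(N).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "median_iqr",
    "validate_cohort",
    "mcid_counts",
    "recovery_subgroups",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "mixed_anova_2x2",
    "spearman",
    "bonferroni",
    "results_table",
]


@dataclass
class TestResult:
    """One inferential test: statistic, Z, p, effect size and bookkeeping."""

    name: str
    statistic: float
    statistic_name: str
    p_value: float
    z_value: float | None = None
    effect_size: float | None = None
    effect_name: str | None = None
    n: tuple | int | None = None
    df: tuple | float | None = None
    direction: str | None = None
    method: str | None = None
    note: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def results_table(results: list[TestResult]) -> pd.DataFrame:
    """Tidy one-row-per-test table, ready for CSV export."""
    return pd.DataFrame([r.to_dict() for r in results])


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def median_iqr(values, method: str = "tukey") -> tuple[float, float, float]:
    """Sample median and quartiles; missing values are excluded.

    ``method='tukey'`` (default) uses Tukey hinges: the quartiles are the
    medians of the lower and upper halves, each half including the overall
    median when n is odd.  ``method='linear'`` uses linear interpolation
    (``numpy.percentile``).
    """
    x = np.asarray(values, dtype=float)
    x = np.sort(x[~np.isnan(x)])
    n = x.size
    if n == 0:
        raise ValueError("no non-missing values")
    med = float(np.median(x))
    if method == "tukey":
        half = (n + 1) // 2
        q1 = float(np.median(x[:half]))
        q3 = float(np.median(x[n - half:]))
    elif method == "linear":
        q1, q3 = map(float, np.percentile(x, [25, 75]))
    else:
        raise ValueError("method must be 'tukey' or 'linear'")
    return med, q1, q3


_RANGES = {
    "arat_w3": (0, 57), "arat_w12": (0, 57),
    "fmue_w3": (0, 66), "fmue_w12": (0, 66),
    "nihss_day0": (0, 42), "mrs": (0, 6),
}


def validate_cohort(rows: pd.DataFrame) -> pd.DataFrame:
    """Range-check score columns; raises on out-of-range values."""
    for col, (lo, hi) in _RANGES.items():
        if col in rows:
            v = rows[col].dropna()
            if ((v < lo) | (v > hi)).any():
                raise ValueError(f"{col} outside [{lo}, {hi}]")
    return rows


def mcid_counts(rows: pd.DataFrame) -> tuple[int, int, int]:
    """Counts of clinically significant week-3 -> week-12 improvements.

    Only rows with both visits enter.  FM-UE criterion: improvement strictly
    greater than 12.4 points.  ARAT criterion: at least 12 points when the
    affected hand is the dominant (right — the cohort is right-handed), at
    least 17 points otherwise.  Returns (arat_count, fmue_count, n_pairs).
    """
    if rows["affected_hand"].isna().any():
        raise ValueError("affected_hand missing for some rows")
    both = rows.dropna(subset=["arat_w12", "fmue_w12"])
    n_pairs = len(both)
    d_arat = both["arat_w12"] - both["arat_w3"]
    d_fmue = both["fmue_w12"] - both["fmue_w3"]
    thr = np.where(both["affected_hand"] == "R", 12, 17)
    arat_count = int(np.sum(d_arat >= thr))
    fmue_count = int(np.sum(d_fmue > 12.4))
    return arat_count, fmue_count, n_pairs


def recovery_subgroups(rows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition week-3-scored patients by initial hand-paresis recovery.

    "Nearly fully recovered" means week-3 ARAT > 55 or FM-UE > 64; "not fully
    recovered" means ARAT < 56 and FM-UE < 65.  The two definitions are exact
    complements (asserted).  Returns (not_recovered, recovered).
    """
    scored = rows.dropna(subset=["arat_w3", "fmue_w3"])
    recovered = scored[(scored["arat_w3"] > 55) | (scored["fmue_w3"] > 64)]
    not_recovered = scored[(scored["arat_w3"] < 56) & (scored["fmue_w3"] < 65)]
    assert len(recovered) + len(not_recovered) == len(scored)
    return not_recovered, recovered


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def _tie_term(ranks: np.ndarray) -> float:
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts**3 - counts))


def mann_whitney_u(x, y, exact_threshold: int = 12) -> TestResult:
    """Two-sample Mann-Whitney U test with midrank ties.

    Reports ``min(U, n1*n2 - U)`` plus the direction (the literature quotes U
    on both conventions' scales, so the direction is explicit).  The Z value
    uses the normal approximation with tie-corrected variance and a 0.5
    continuity correction; the effect size is r = |Z| / sqrt(n1 + n2).  When
    ``n1 + n2 <= exact_threshold`` the p-value comes from exhaustive
    enumeration of all group assignments of the pooled values (two-sided:
    total probability of |U - n1*n2/2| at least as extreme).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    R1 = ranks[:n1].sum()
    U1 = R1 - n1 * (n1 + 1) / 2  # x-favourable convention
    mu = n1 * n2 / 2
    N = n1 + n2
    sigma2 = n1 * n2 / 12 * ((N + 1) - _tie_term(ranks) / (N * (N - 1)))
    dev = abs(U1 - mu)
    if sigma2 > 0:
        z = max(dev - 0.5, 0.0) / np.sqrt(sigma2)
    else:
        z = 0.0
    if N <= exact_threshold:
        devs = []
        for comb in itertools.combinations(range(N), n1):
            r1 = ranks[list(comb)].sum()
            devs.append(abs(r1 - n1 * (n1 + 1) / 2 - mu))
        devs = np.asarray(devs)
        p = float(np.mean(devs >= dev - 1e-12))
        method = "exact enumeration"
    else:
        p = float(2 * stats.norm.sf(z))
        p = min(p, 1.0)
        method = "normal approximation, tie-corrected, continuity-corrected"
    direction = "x > y" if U1 > mu else ("x < y" if U1 < mu else "none")
    return TestResult(
        name="Mann-Whitney U",
        statistic=float(min(U1, n1 * n2 - U1)),
        statistic_name="U",
        p_value=p,
        z_value=float(z),
        effect_size=float(z / np.sqrt(N)),
        effect_name="r",
        n=(n1, n2),
        direction=direction,
        method=method,
    )


def wilcoxon_signed_rank(
    x, y=None, zero_method: str = "drop", exact_threshold: int = 14
) -> TestResult:
    """Paired Wilcoxon signed-rank test.

    Pass differences directly or two paired samples.  Zero differences are
    dropped by default (``zero_method='pratt'`` ranks them first, then
    discards their ranks).  Midranks are used on |d|; Z uses the
    tie-corrected variance (no continuity correction); r = |Z| / sqrt(n)
    with n the number of nonzero pairs.  For n <= ``exact_threshold`` the
    p-value enumerates all 2^n sign assignments.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[~np.isnan(d)]
    nz = d != 0
    if not nz.any():
        return TestResult(
            name="Wilcoxon signed-rank", statistic=np.nan, statistic_name="W",
            p_value=np.nan, n=0, note="no nonzero pairs; test undefined",
        )
    if zero_method == "drop":
        d = d[nz]
        ranks = stats.rankdata(np.abs(d))
    elif zero_method == "pratt":
        ranks = stats.rankdata(np.abs(d))
        ranks, d = ranks[nz], d[nz]
    else:
        raise ValueError("zero_method must be 'drop' or 'pratt'")
    n = d.size
    w_plus = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2  # = n(n+1)/4 without zeros
    sigma2 = np.sum(ranks**2) / 4  # tie-corrected: reduces to n(n+1)(2n+1)/24
    dev = abs(w_plus - mu)
    z = dev / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    if n <= exact_threshold:
        devs = np.abs(_signflip_sums(ranks) - mu)
        p = float(np.mean(devs >= dev - 1e-12))
        method = "exact sign-flip enumeration"
    else:
        p = min(float(2 * stats.norm.sf(z)), 1.0)
        method = "normal approximation, tie-corrected"
    return TestResult(
        name="Wilcoxon signed-rank",
        statistic=w_plus,
        statistic_name="W+",
        p_value=p,
        z_value=float(z),
        effect_size=float(z / np.sqrt(n)),
        effect_name="r",
        n=n,
        direction="positive" if w_plus > mu else ("negative" if w_plus < mu else "none"),
        method=method,
    )


def _signflip_sums(ranks: np.ndarray) -> np.ndarray:
    """Sums of positive-signed ranks over all 2^n sign assignments."""
    sums = np.zeros(1)
    for r in ranks:
        sums = np.concatenate([sums, sums + r])
    return sums


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------


def mixed_anova_2x2(groups, y_region1, y_region2) -> pd.DataFrame:
    """2 x 2 mixed-design ANOVA (between: group, within: region).

    Uses the sum/difference decomposition: with subject means
    ``s = (y1 + y2) / 2`` and differences ``d = y1 - y2``, the group effect is
    the one-way ANOVA on ``s`` (error: subjects within groups), the region
    effect tests the unweighted grand mean of ``d`` against zero, and the
    interaction is the group contrast on ``d`` (both against the
    region-by-subject error).  Unequal group sizes are allowed (Type III
    marginality); subjects with a missing measure are excluded listwise with
    a logged count.  Partial eta squared is SS_effect / (SS_effect +
    SS_error) within each error stratum.
    """
    groups = np.asarray(groups)
    y1 = np.asarray(y_region1, dtype=float)
    y2 = np.asarray(y_region2, dtype=float)
    ok = ~(np.isnan(y1) | np.isnan(y2))
    if not ok.all():
        warnings.warn(f"excluded {np.sum(~ok)} subject(s) with missing measures")
        groups, y1, y2 = groups[ok], y1[ok], y2[ok]
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError("between-subject factor must have exactly 2 levels")
    g1, g2 = (groups == levels[0]), (groups == levels[1])
    n1, n2 = int(g1.sum()), int(g2.sum())
    N = n1 + n2
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    s = (y1 + y2) / 2.0
    d = y1 - y2
    inv = 1 / n1 + 1 / n2

    # between-subjects stratum (factor of 2: two repeated measures per subject)
    ss_group = 2 * (s[g1].mean() - s[g2].mean()) ** 2 / inv
    ss_err_b = 2 * (np.sum((s[g1] - s[g1].mean()) ** 2) + np.sum((s[g2] - s[g2].mean()) ** 2))

    # within-subjects stratum (d carries the region contrast; /2 for y-scale SS)
    grand_d = (d[g1].mean() + d[g2].mean()) / 2.0
    ss_region = grand_d**2 / (inv / 4) / 2
    ss_inter = (d[g1].mean() - d[g2].mean()) ** 2 / inv / 2
    ss_err_w = (np.sum((d[g1] - d[g1].mean()) ** 2) + np.sum((d[g2] - d[g2].mean()) ** 2)) / 2

    df_err = N - 2
    rows = []
    for name, ss, ss_err in (
        ("group", ss_group, ss_err_b),
        ("region", ss_region, ss_err_w),
        ("interaction", ss_inter, ss_err_w),
    ):
        if ss_err > 0:
            F = ss / (ss_err / df_err)
            p = float(stats.f.sf(F, 1, df_err))
        else:
            F, p = np.inf, 0.0
        denom = ss + ss_err
        rows.append(
            {
                "effect": name,
                "SS": ss,
                "SS_error": ss_err,
                "df1": 1,
                "df2": df_err,
                "F": F,
                "p_value": p,
                "eta_p2": ss / denom if denom > 0 else np.nan,
                "n": (n1, n2),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


def spearman(x, y, control=None, exact_threshold: int = 9) -> TestResult:
    """Spearman rank correlation, optionally partial (first order).

    ``rho`` is the Pearson correlation of midranks.  With ``control`` the
    first-order partial correlation of the rank-transformed triple is
    returned (df = n - 3); zero residual variance in either variable makes
    the partial correlation undefined and is signalled explicitly.  The
    p-value uses the t approximation, or exhaustive permutation of the y
    ranks when ``n <= exact_threshold`` (plain correlation only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if control is not None:
        z = np.asarray(control, dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
        x, y, z = x[ok], y[ok], z[ok]
    else:
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete observations")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if control is None:
        rho = _pearson(rx, ry)
        df = n - 2
        name, note = "Spearman rho", None
    else:
        rz = stats.rankdata(z)
        rxy, rxz, ryz = _pearson(rx, ry), _pearson(rx, rz), _pearson(ry, rz)
        denom = (1 - rxz**2) * (1 - ryz**2)
        if denom <= 1e-14:
            return TestResult(
                name="partial Spearman rho", statistic=np.nan,
                statistic_name="rho_partial", p_value=np.nan, n=n,
                note="zero residual variance after controlling; undefined",
            )
        rho = (rxy - rxz * ryz) / np.sqrt(denom)
        df = n - 3
        name, note = "partial Spearman rho", None
    if control is None and n <= exact_threshold:
        obs = abs(rho)
        hits = tot = 0
        for perm in itertools.permutations(ry):
            tot += 1
            if abs(_pearson(rx, np.asarray(perm))) >= obs - 1e-12:
                hits += 1
        p = hits / tot
        method = "exact permutation enumeration"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt(df / (1 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df))
        method = "t approximation"
    return TestResult(
        name=name, statistic=float(rho),
        statistic_name="rho" if control is None else "rho_partial",
        p_value=p, n=n, df=df, method=method, note=note,
        effect_size=float(rho), effect_name="rho",
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        return np.nan
    return float(np.sum(a * b) / denom)


def bonferroni(p_values, m: int | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni correction: threshold alpha/m, decisions next to raw p."""
    p = np.asarray(p_values, dtype=float)
    m = int(m if m is not None else p.size)
    if m < 1:
        raise ValueError("m must be >= 1")
    thr = alpha / m
    return pd.DataFrame(
        {
            "p_raw": p,
            "p_adjusted": np.minimum(p * m, 1.0),
            "alpha_corrected": thr,
            "reject": p < thr,
        }
    )
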