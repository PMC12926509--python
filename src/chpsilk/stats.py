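"""Small-sample group comparisons for turnover rates.

Cohorts in CSF labelling studies are tiny (n of 4-10 per arm), so the
primary comparisons use exact machinery: the Mann-Whitney U null
distribution is enumerated by dynamic programming (no ties) or approximated
by seeded Monte-Carlo permutation (ties or larger n); Spearman correlation
p-values are exact by full rank-permutation enumeration up to n = 8; the
Welch t-test uses the Welch-Satterthwaite degrees of freedom.  A
Shapiro-Wilk normality screen is exposed as a hook (it gates nothing by
default).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "TestResult",
    "mann_whitney_exact",
    "spearman_corr",
    "welch_t",
    "shapiro_wilk",
    "holm_adjust",
    "compare_groups",
]


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    statistic: float
    p_value: float
    method: str  # exact | normal_approx | permutation | t_approx
    n1: int
    n2: int
    alternative: str = "two_sided"

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError(f"p_value out of [0,1]: {self.p_value}")


def u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of each value of the Mann-Whitney U statistic under the null.

    ``counts[u]`` is the number of the C(n1+n2, n1) equally likely rank
    assignments with U = u, for u in 0..n1*n2, via the standard recurrence
    ``N(u; m, n) = N(u - n; m-1, n) + N(u; m, n-1)``.  The distribution sums
    to C(n1+n2, n1) and is symmetric about n1*n2/2.
    """
    max_u = n1 * n2
    # counts[m] holds N(u; m, n) for the current n; start at n = 0 (U = 0 only)
    counts = np.zeros((n1 + 1, max_u + 1), dtype=np.int64)
    counts[:, 0] = 1
    for n in range(1, n2 + 1):
        new = np.zeros_like(counts)
        new[0, 0] = 1
        for m in range(1, n1 + 1):
            new[m] = counts[m]  # N(u; m, n-1)
            new[m, n:] += new[m - 1, : max_u + 1 - n]  # N(u-n; m-1, n)
        counts = new
    return counts[n1]


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(U_x, tie count) where U_x counts pairs with x_i < y_j plus half ties."""
    less = np.sum(x[:, None] < y[None, :])
    ties = np.sum(x[:, None] == y[None, :])
    return float(less) + 0.5 * float(ties), float(ties)


def mann_whitney_exact(
    x,
    y,
    alternative: str = "two_sided",
    exact_max_n: int = 25,
    n_permutations: int = 100_000,
    seed: int = 0,
) -> TestResult:
    """Mann-Whitney U test with an exact small-sample null.

    The reported statistic is the smaller of the two one-sided U statistics
    (so complete separation prints as U = 0).  With no ties and
    ``n1 + n2 <= exact_max_n`` the p-value is exact from the enumerated null
    distribution; the two-sided p is ``2 * min(lower tail, upper tail)``
    capped at 1.  With ties or larger samples a seeded Monte-Carlo
    permutation test is used instead (``method = "permutation"``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    u_x, ties = _u_statistic(x, y)
    u_report = min(u_x, n1 * n2 - u_x)

    if ties == 0 and n1 + n2 <= exact_max_n:
        counts = u_null_counts(n1, n2).astype(float)
        total = counts.sum()
        u_int = int(round(u_x))
        lower = counts[: u_int + 1].sum() / total
        upper = counts[u_int:].sum() / total
        if alternative == "two_sided":
            p = min(1.0, 2.0 * min(lower, upper))
        elif alternative == "less":  # x tends below y -> small U_x? U_x counts x<y pairs
            p = upper
        elif alternative == "greater":
            p = lower
        else:
            raise ValidationError(f"unknown alternative {alternative!r}")
        return TestResult("U", u_report, p, "exact", n1, n2, alternative)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        u_p, _ = _u_statistic(perm[:n1], perm[n1:])
        if alternative == "two_sided":
            hit = abs(u_p - n1 * n2 / 2) >= abs(u_x - n1 * n2 / 2) - 1e-12
        elif alternative == "less":
            hit = u_p >= u_x - 1e-12
        else:
            hit = u_p <= u_x + 1e-12
        count += hit
    p = (count + 1) / (n_permutations + 1)
    return TestResult("U", u_report, min(1.0, p), "permutation", n1, n2, alternative)


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(np.sum(rx**2)) * float(np.sum(ry**2)))
    if denom == 0:
        raise ValidationError("Spearman rho undefined for a constant vector")
    return float(np.sum(rx * ry)) / denom


def spearman_corr(x, y, exact_max_n: int = 8) -> TestResult:
    """Spearman rank correlation with an exact permutation p for small n.

    rho is the Pearson correlation of mid-ranks.  For ``n <= exact_max_n``
    the two-sided p enumerates all n! permutations of one rank vector;
    larger n uses the t approximation with ``df = n - 2``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("paired vectors required")
    n = x.size
    if n < 3:
        raise ValidationError("Spearman correlation requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _spearman_rho(rx, ry)

    if n <= exact_max_n:
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _spearman_rho(rx, ry[list(perm)])
            hits += abs(r) >= abs(rho) - 1e-12
            total += 1
        return TestResult("rho", rho, hits / total, "exact", n, 0)
    if abs(rho) >= 1.0:
        return TestResult("rho", rho, 0.0, "t_approx", n, 0)
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return TestResult("rho", rho, min(1.0, p), "t_approx", n, 0)


def welch_t(x, y, alternative: str = "two_sided") -> TestResult:
    """Unpaired t-test with Welch's correction (unequal variances).

    ``t = (mean x - mean y) / sqrt(s1^2/n1 + s2^2/n2)`` with
    Welch-Satterthwaite (non-integer) degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValidationError("Welch t-test requires n >= 2 per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        if x.mean() == y.mean():
            raise ValidationError("t undefined: zero variance in both groups, equal means")
        t = math.inf if x.mean() > y.mean() else -math.inf
        return TestResult("t", t, 0.0, "t_approx", n1, n2, alternative)
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    if alternative == "two_sided":
        p = 2 * sps.t.sf(abs(t), df=df)
    elif alternative == "greater":
        p = sps.t.sf(t, df=df)
    elif alternative == "less":
        p = sps.t.cdf(t, df=df)
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    return TestResult("t", float(t), float(min(1.0, p)), "t_approx", n1, n2, alternative)


def welch_df(x, y) -> float:
    """Welch-Satterthwaite degrees of freedom (exposed for reporting)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    n1, n2 = x.size, y.size
    se2 = v1 / n1 + v2 / n2
    return float(se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)))


def shapiro_wilk(x) -> TestResult:
    """Normality screening hook; delegates to the standard Shapiro-Wilk test."""
    x = np.asarray(x, dtype=float)
    w, p = sps.shapiro(x)
    return TestResult("W", float(w), float(p), "exact", x.size, 0)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment (off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def compare_groups(
    rates: pd.DataFrame,
    quantities: tuple[str, ...] = ("fsr_pct_per_h", "fcr_per_h"),
    group_col: str = "group",
    pairs: list[tuple[str, str]] | None = None,
    production: pd.DataFrame | None = None,
    seed: int = 0,
    holm: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run all pairwise Mann-Whitney comparisons and optional Spearman correlations.

    Parameters
    ----------
    rates
        Rates table (one row per subject x peptide) with a ``group_col``
        column, as produced by :func:`chpsilk.kinetics.results_to_frame`.
    production
        Optional table (subject_id, production_ml_per_h); when given, FSR is
        correlated against CSF production per peptide (Spearman).

    Returns
    -------
    (comparisons, correlations)
        comparisons: peptide_id, quantity, group_a, group_b, n_a, n_b,
        n_excluded_a, n_excluded_b, statistic, p, method.
        correlations: peptide_id, quantity, n, rho, p, method.
    """
    if group_col not in rates.columns:
        raise ValidationError(f"rates table lacks a {group_col!r} column")
    groups = sorted(rates[group_col].dropna().unique())
    if pairs is None:
        pairs = list(itertools.combinations(groups, 2))
    else:
        for a, b in pairs:
            if a not in groups or b not in groups:
                raise ValidationError(f"unknown group label in pair ({a}, {b})")

    comp_rows = []
    for peptide in sorted(rates["peptide_id"].unique()):
        sub = rates[rates["peptide_id"] == peptide]
        for quantity in quantities:
            for ga, gb in pairs:
                a_all = sub.loc[sub[group_col] == ga, quantity]
                b_all = sub.loc[sub[group_col] == gb, quantity]
                a = a_all.dropna().to_numpy()
                b = b_all.dropna().to_numpy()
                row = {
                    "peptide_id": peptide,
                    "quantity": quantity,
                    "group_a": ga,
                    "group_b": gb,
                    "n_a": a.size,
                    "n_b": b.size,
                    "n_excluded_a": int(a_all.size - a.size),
                    "n_excluded_b": int(b_all.size - b.size),
                }
                if a.size == 0 or b.size == 0:
                    row.update(statistic=math.nan, p=math.nan, method="skipped_empty_group")
                else:
                    res = mann_whitney_exact(a, b, seed=seed)
                    row.update(statistic=res.statistic, p=res.p_value, method=res.method)
                comp_rows.append(row)
    comparisons = pd.DataFrame(comp_rows)
    if holm and len(comparisons):
        ok = comparisons["p"].notna()
        comparisons.loc[ok, "p_holm"] = holm_adjust(comparisons.loc[ok, "p"].to_numpy())

    corr_rows = []
    if production is not None:
        prod = production.set_index("subject_id")["production_ml_per_h"]
        for peptide in sorted(rates["peptide_id"].unique()):
            sub = rates[rates["peptide_id"] == peptide]
            merged = sub.assign(production=sub["subject_id"].map(prod)).dropna(
                subset=["fsr_pct_per_h", "production"]
            )
            if len(merged) < 3:
                continue
            res = spearman_corr(merged["production"].to_numpy(), merged["fsr_pct_per_h"].to_numpy())
            corr_rows.append(
                {
                    "peptide_id": peptide,
                    "quantity": "fsr_pct_per_h",
                    "n": res.n1,
                    "rho": res.statistic,
                    "p": res.p_value,
                    "method": res.method,
                }
            )
    correlations = pd.DataFrame(
        corr_rows, columns=["peptide_id", "quantity", "n", "rho", "p", "method"]
    )
    return comparisons, correlations
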