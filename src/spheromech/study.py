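"""Longitudinal treated-vs-control statistics for the spheroid study.

The study design is 3 culture groups (LN229 glioblastoma monoculture, human
astrocyte (HA) monoculture, 1:1 co-culture) x 2 conditions (control,
TMZ-treated) x 3 time points (days 0, 4, 7), with replicate measurements per
cell.  Group comparisons are nonparametric: Kruskal-Wallis across days
within a (group, condition), Mann-Whitney U between conditions at each
(group, day), both at alpha = 0.05 on raw (uncorrected) p-values.  The
drug effect is summarized by the treated/control ratio of cell means per
(group, day).

Implementation notes
--------------------
* The exact two-sided Mann-Whitney p-value is defined as
  ``2 * min(P(U1 <= u), P(U1 >= u))`` capped at 1.  The tie-free exact null
  distribution is computed from the classic rank-count recurrence
  ``N(u; n, m) = N(u - m; n - 1, m) + N(u; n, m - 1)``; with ties,
  ``mode="exact"`` enumerates all C(n+m, n) labelings on mid-ranks, while
  ``mode="auto"`` falls back to the tie-corrected normal approximation.
* Kruskal-Wallis uses the rank formula with the usual tie correction and a
  chi-square (k-1 df) tail by default; an exact permutation option
  enumerates all group assignments for small total n.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError

__all__ = [
    "GROUPS",
    "CONDITIONS",
    "DAYS",
    "METRICS",
    "GroupComparison",
    "validate_study_table",
    "mann_whitney_u",
    "kruskal_wallis",
    "normalize_treated_to_control",
    "summarize_study",
]

GROUPS = ("LN229", "HA", "CO")
CONDITIONS = ("control", "treated")
DAYS = (0, 4, 7)
METRICS = ("wave_speed_mps", "young_modulus_pa", "brillouin_shift_ghz", "eq_diameter_um")

STUDY_COLUMNS = ["group", "condition", "day", "replicate", "metric", "value"]


@dataclass
class GroupComparison:
    """One statistical contrast: H or U statistic, p-value, significance flag."""

    contrast: str
    statistic_name: Literal["H", "U"]
    statistic: float
    p_value: float
    method: Literal["exact", "chi2_approx", "normal_approx"]
    significant: bool
    alpha: float
    extra: dict | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ConfigurationError(f"p-value {self.p_value} outside [0, 1]")


def validate_study_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format study table contract; returns the table."""
    missing = [c for c in STUDY_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(f"study table missing columns {missing}")
    if table.duplicated(subset=["group", "condition", "day", "replicate", "metric"]).any():
        raise ConfigurationError("duplicate (group, condition, day, replicate, metric) keys")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ConfigurationError("study values must be finite")
    bad_days = set(table["day"]) - set(DAYS)
    if bad_days:
        raise ConfigurationError(f"days {sorted(bad_days)} outside the design set {DAYS}")
    bad_cond = set(table["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ConfigurationError(f"unknown conditions {sorted(bad_cond)}")
    return table


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple:
    """Tie-free null counts of U1 = (rank sum of the n-group) - n(n+1)/2.

    Entry u of the returned tuple is the number of n-subsets of ranks
    1..n+m with that U value; the total is C(n+m, n).
    """
    if n == 0 or m == 0:
        return (1,)
    a = _u_counts(n - 1, m)  # largest rank goes to the n-group: U gains m... see recurrence
    b = _u_counts(n, m - 1)
    out = [0] * (n * m + 1)
    for u, c in enumerate(a):
        out[u + m] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def _rank_sums(values: np.ndarray, n: int) -> tuple[float, float]:
    """(U1, tie-corrected sigma of U1) for the first n of the pooled values."""
    N = len(values)
    ranks = sps.rankdata(values)
    u1 = float(ranks[:n].sum() - n * (n + 1) / 2)
    m = N - n
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    return u1, float(np.sqrt(max(var, 0.0)))


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    mode: Literal["auto", "exact", "normal"] = "auto",
    *,
    alpha: float = 0.05,
    continuity: bool = True,
    contrast: str = "a vs b",
    max_exact_n: int = 14,
) -> GroupComparison:
    """Two-sided Mann-Whitney U test; reports U = min(U1, U2).

    ``auto`` uses the exact tie-free distribution when n + m <= ``max_exact_n``
    and no ties are present, otherwise the tie-corrected normal approximation
    with continuity correction.  ``exact`` forces full enumeration of all
    C(n+m, n) labelings (mid-ranks; handles ties).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ConfigurationError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < n + m
    u1, sigma = _rank_sums(pooled, n)
    u2 = n * m - u1
    u = min(u1, u2)

    # The rank-count recurrence is cheap at any size, so forced exact mode
    # always uses it on tie-free data; `auto` only switches to it for small
    # samples, and tied data must fall back to enumeration or the normal
    # approximation.
    use_exact_counts = not has_ties and (
        mode == "exact" or (mode == "auto" and n + m <= max_exact_n)
    )
    if use_exact_counts:
        counts = np.asarray(_u_counts(n, m), dtype=float)
        total = comb(n + m, n)
        ui = int(round(u1))
        p_le = counts[: ui + 1].sum() / total
        p_ge = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    elif mode == "exact":
        if n + m > max_exact_n:
            raise ConfigurationError(f"exact enumeration limited to n + m <= {max_exact_n}")
        ranks = sps.rankdata(pooled)
        offset = n * (n + 1) / 2
        null_u1 = np.array(
            [ranks[list(idx)].sum() - offset for idx in itertools.combinations(range(n + m), n)]
        )
        eps = 1e-9
        p_le = np.mean(null_u1 <= u1 + eps)
        p_ge = np.mean(null_u1 >= u1 - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        if sigma == 0:  # all pooled values identical
            p, z = 1.0, 0.0
        else:
            d = u1 - n * m / 2.0
            if continuity and d != 0:
                d -= 0.5 * np.sign(d)
            z = d / sigma
            p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "normal_approx"

    extra = {"u1": float(u1), "u2": float(u2), "n": n, "m": m, "ties": bool(has_ties)}
    if method == "normal_approx":
        extra["z"] = float(z)
    return GroupComparison(
        contrast=contrast,
        statistic_name="U",
        statistic=float(u),
        p_value=float(p),
        method=method,
        significant=bool(p < alpha),
        alpha=alpha,
        extra=extra,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def _kw_statistic(pooled_ranks: np.ndarray, sizes: Sequence[int], tie_correction: float) -> float:
    N = len(pooled_ranks)
    h = 0.0
    start = 0
    for ni in sizes:
        r = pooled_ranks[start : start + ni].sum()
        h += r * r / ni
        start += ni
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    return h / tie_correction if tie_correction > 0 else 0.0


def kruskal_wallis(
    samples: Sequence[Sequence[float]],
    *,
    alpha: float = 0.05,
    method: Literal["chi2", "exact"] = "chi2",
    contrast: str = "k-group",
    max_exact_n: int = 10,
) -> GroupComparison:
    """Kruskal-Wallis H test with tie correction.

    ``H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1)``, divided by the tie factor
    ``1 - sum(t^3 - t)/(N^3 - N)``.  The p-value uses the chi-square tail
    with k-1 df, or exact permutation (all assignments of the pooled values
    to groups) for total n <= ``max_exact_n``.
    """
    groups = [np.asarray(g, dtype=float) for g in samples]
    if len(groups) < 2:
        raise ConfigurationError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ConfigurationError("empty group")
    if any(len(g) < 2 for g in groups):
        raise ConfigurationError("each group needs at least 2 observations")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_c = 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N)

    if tie_c <= 0:  # all values identical
        h, p, method_used = 0.0, 1.0, "chi2_approx" if method == "chi2" else "exact"
    else:
        h = _kw_statistic(ranks, sizes, tie_c)
        if method == "chi2":
            p = float(sps.chi2.sf(h, len(groups) - 1))
            method_used = "chi2_approx"
        elif method == "exact":
            if N > max_exact_n:
                raise ConfigurationError(f"exact permutation limited to total n <= {max_exact_n}")
            null_h = [
                _kw_statistic(ranks[list(perm)], sizes, tie_c)
                for perm in _group_assignments(N, sizes)
            ]
            p = float(np.mean(np.asarray(null_h) >= h - 1e-12))
            method_used = "exact"
        else:
            raise ConfigurationError(f"unknown method {method!r}")

    return GroupComparison(
        contrast=contrast,
        statistic_name="H",
        statistic=float(h),
        p_value=p,
        method=method_used,
        significant=bool(p < alpha),
        alpha=alpha,
        extra={"sizes": sizes, "tie_correction": tie_c},
    )


def _group_assignments(N: int, sizes: Sequence[int]):
    """Yield index orderings (group1 indices, then group2, ...) over all
    distinct assignments of N items to groups of the given sizes."""

    def rec(remaining: tuple, sizes_left: list):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for pick in itertools.combinations(remaining, k):
            rest = tuple(x for x in remaining if x not in pick)
            for tail in rec(rest, sizes_left[1:]):
                yield pick + tail

    yield from rec(tuple(range(N)), list(sizes))


# ---------------------------------------------------------------------------
# Normalization and the study report


def normalize_treated_to_control(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Treated/control ratio of cell means per (group, day), with propagated SD.

    ``ratio = mean_treated / mean_control``; the SD uses first-order error
    propagation, ``ratio * sqrt((sd_t/m_t)^2 + (sd_c/m_c)^2)``.  Cells with a
    missing condition or non-positive control mean are flagged invalid, not
    dropped silently.  Day-0 ratios are reported as computed (not rebased).
    """
    validate_study_table(table)
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ConfigurationError(f"no rows for metric {metric!r}")
    rows = []
    groups = [g for g in GROUPS if g in set(sub["group"])] or sorted(set(sub["group"]))
    for group in groups:
        for day in sorted(set(sub["day"])):
            cell = sub[(sub["group"] == group) & (sub["day"] == day)]
            # sorted so the aggregation is invariant to table row order
            t = np.sort(cell[cell["condition"] == "treated"]["value"].to_numpy())
            c = np.sort(cell[cell["condition"] == "control"]["value"].to_numpy())
            row = {"group": group, "day": int(day), "metric": metric,
                   "n_treated": len(t), "n_control": len(c)}
            if len(t) == 0 or len(c) == 0:
                row.update(ratio=np.nan, ratio_sd=np.nan, valid=False, note="missing condition")
            else:
                mt, mc = float(t.mean()), float(c.mean())
                st = float(t.std(ddof=1)) if len(t) > 1 else 0.0
                sc = float(c.std(ddof=1)) if len(c) > 1 else 0.0
                if mc <= 0:
                    row.update(ratio=np.nan, ratio_sd=np.nan, valid=False,
                               note="control mean not positive")
                else:
                    ratio = mt / mc
                    if mt > 0:
                        sd = abs(ratio) * np.sqrt((st / mt) ** 2 + (sc / mc) ** 2)
                    else:
                        sd = np.nan
                    row.update(ratio=ratio, ratio_sd=sd, valid=True, note="")
            rows.append(row)
    return pd.DataFrame(rows)


def _comparison_record(c: GroupComparison) -> dict:
    return {
        "contrast": c.contrast,
        "statistic_name": c.statistic_name,
        "statistic": float(c.statistic),
        "p_value": float(c.p_value),
        "method": c.method,
        "significant": bool(c.significant),
    }


def summarize_study(
    table: pd.DataFrame,
    metric: str | None = None,
    *,
    alpha: float = 0.05,
    mwu_mode: Literal["auto", "exact", "normal"] = "auto",
) -> dict:
    """Machine-readable longitudinal report for one metric.

    Per (group, condition): Kruskal-Wallis across days.  Per (group, day):
    Mann-Whitney U of control vs treated.  Plus the treated/control
    normalized summary.  Design cells with fewer than 2 replicates are
    excluded with a warning.  The report depends only on the table contents,
    not the row order.
    """
    validate_study_table(table)
    metrics = sorted(set(table["metric"]))
    if metric is None:
        if len(metrics) != 1:
            raise ConfigurationError(f"table holds metrics {metrics}; specify one")
        metric = metrics[0]
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ConfigurationError(f"no rows for metric {metric!r}")

    notes: list[str] = []
    groups = [g for g in GROUPS if g in set(sub["group"])] or sorted(set(sub["group"]))
    days = sorted(set(sub["day"]))

    def cell_values(group, condition, day):
        v = sub[
            (sub["group"] == group) & (sub["condition"] == condition) & (sub["day"] == day)
        ]["value"].to_numpy(dtype=float)
        return np.sort(v)  # row-order invariance

    kw_records = []
    for group in groups:
        for condition in CONDITIONS:
            per_day = []
            for day in days:
                v = cell_values(group, condition, day)
                if len(v) >= 2:
                    per_day.append(v)
                elif len(v) > 0:
                    notes.append(f"excluded {group}/{condition}/day{day}: <2 replicates")
            if len(per_day) < 2:
                notes.append(f"skipped KW for {group}/{condition}: <2 usable days")
                continue
            c = kruskal_wallis(per_day, alpha=alpha, contrast=f"{group}/{condition} across days")
            rec = _comparison_record(c)
            rec.update(group=group, condition=condition, n_days=len(per_day))
            kw_records.append(rec)

    mwu_records = []
    for group in groups:
        for day in days:
            a = cell_values(group, "control", day)
            b = cell_values(group, "treated", day)
            if len(a) < 2 or len(b) < 2:
                notes.append(f"skipped U test for {group}/day{day}: <2 replicates in a condition")
                continue
            c = mann_whitney_u(
                a, b, mode=mwu_mode, alpha=alpha, contrast=f"{group}/day{day} control vs treated"
            )
            rec = _comparison_record(c)
            rec.update(group=group, day=int(day))
            mwu_records.append(rec)

    norm = normalize_treated_to_control(table, metric)
    norm_records = [
        {k: (float(v) if isinstance(v, (int, float, np.floating)) and k not in ("day",) else v)
         for k, v in r.items()}
        for r in norm.to_dict(orient="records")
    ]
    for r in norm_records:
        r["day"] = int(r["day"])
        r["valid"] = bool(r["valid"])

    for msg in notes:
        warnings.warn(msg, stacklevel=2)
    return {
        "metric": metric,
        "alpha": float(alpha),
        "kruskal_wallis": kw_records,
        "mann_whitney": mwu_records,
        "normalization": norm_records,
        "warnings": notes,
    }
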