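"""Group-comparison statistics: rank tests and nested one-way ANOVA.

The nested ANOVA is the spreadsheet-style hierarchical decomposition used
for grouped electrophysiology data: observations nest in cells, cells in
animals, animals in groups.  Each level's mean square is tested against the
mean square of the level nested immediately below it, and variance
components are estimated by the method of moments with exact
unbalanced-design expected-mean-square coefficients computed from the unit
counts (the average-coefficient algebra of the classical nested-ANOVA
spreadsheets).  Negative component estimates are clamped to zero before
percentages are formed; the raw values are retained.

Rank tests are thin wrappers around scipy with the conventions fixed:
two-sided p values, exact enumeration for small samples (combined n <= 16
for Mann–Whitney, <= 15 pairs for Wilcoxon) and tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mann_whitney",
    "wilcoxon_paired",
    "NestedAnova",
    "NestedAnovaResults",
]


# --------------------------------------------------------------------------
# rank tests
# --------------------------------------------------------------------------

def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact null distribution when the combined sample size is <= 16 and there
    are no ties; tie-corrected normal approximation (with continuity
    correction) otherwise.  Returns (U of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= 16 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_paired(x, y) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (standard convention); exact for <= 15
    non-zero pairs without ties in |d|.  All-zero differences give p = 1.
    Returns (W, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must be paired (equal length)")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1 by convention")
        return 0.0, 1.0
    if d.size <= 15:
        # full sign-pattern enumeration (handles ties in |d| exactly)
        method = stats.PermutationMethod(n_resamples=2**15)
    else:
        method = "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# nested one-way ANOVA
# --------------------------------------------------------------------------

@dataclass
class _LevelResult:
    name: str
    ss: float
    df: int
    ms: float
    f: float
    p: float
    var_component_raw: float
    var_component: float  # clamped at 0
    var_percent: float


class NestedAnovaResults:
    """Results of a nested one-way ANOVA.

    ``table`` lists, per level (top grouping first, residual last), the sum
    of squares, degrees of freedom, mean square, F statistic and p value;
    ``variance_components`` the method-of-moments estimates and their
    percentages of total (clamped components sum to 100%).
    """

    def __init__(self, model, levels: list[_LevelResult]):
        self.model = model
        self.levels = levels

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [lv.name for lv in self.levels],
                "ss": [lv.ss for lv in self.levels],
                "df": [lv.df for lv in self.levels],
                "ms": [lv.ms for lv in self.levels],
                "F": [lv.f for lv in self.levels],
                "p": [lv.p for lv in self.levels],
            }
        )

    @property
    def variance_components(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [lv.name for lv in self.levels],
                "var_component_raw": [lv.var_component_raw for lv in self.levels],
                "var_component": [lv.var_component for lv in self.levels],
                "percent_of_total": [lv.var_percent for lv in self.levels],
            }
        )

    @property
    def p_values(self) -> dict[str, float]:
        return {lv.name: lv.p for lv in self.levels if not np.isnan(lv.p)}

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "variance_components": self.variance_components.to_dict(orient="records"),
        }

    def summary(self) -> str:
        lines = ["Nested one-way ANOVA", "=" * 64]
        t = self.table
        lines.append(
            f"{'source':<14}{'SS':>12}{'df':>6}{'MS':>12}{'F':>10}{'p':>10}"
        )
        for _, r in t.iterrows():
            f_str = f"{r.F:.4g}" if np.isfinite(r.F) else "--"
            p_str = f"{r.p:.4g}" if np.isfinite(r.p) else "--"
            lines.append(
                f"{r.source:<14}{r.ss:>12.5g}{int(r.df):>6}{r.ms:>12.5g}"
                f"{f_str:>10}{p_str:>10}"
            )
        lines.append("-" * 64)
        for _, r in self.variance_components.iterrows():
            lines.append(
                f"{r.source:<14} variance component {r.var_component:>10.5g}"
                f"  ({r.percent_of_total:5.2f}% of total)"
            )
        return "\n".join(lines)


class NestedAnova:
    """Nested one-way ANOVA model for fully hierarchical designs.

    Parameters
    ----------
    values : array-like
        Observations.
    factors : sequence of array-likes
        Hierarchical classification labels, outermost (group) first, e.g.
        ``[groups]`` for a plain one-way layout, ``[groups, animals]`` for a
        two-level nested design, ``[groups, animals, cells]`` for a
        three-level design.  Labels are combined cumulatively, so subgroup
        labels need not be globally unique.  Unbalanced designs are allowed.
    """

    LEVEL_NAMES = ["group", "subgroup", "subsubgroup", "level4"]

    def __init__(self, values, factors):
        self.y = np.asarray(values, dtype=float)
        if self.y.ndim != 1 or self.y.size == 0:
            raise ValueError("values must be a non-empty 1-d array")
        self.factors = [np.asarray(f) for f in factors]
        if not 1 <= len(self.factors) <= 4:
            raise ValueError("need 1-4 nesting levels")
        for f in self.factors:
            if f.shape != self.y.shape:
                raise ValueError("every factor must match values in length")
        # cumulative paths: unit id at level l is the tuple of labels [0..l]
        n = self.y.size
        self.paths = []
        for l in range(len(self.factors)):
            path = [
                tuple(str(self.factors[j][i]) for j in range(l + 1))
                for i in range(n)
            ]
            arr = np.empty(n, dtype=object)
            arr[:] = path
            self.paths.append(arr)
        if len(np.unique(self.paths[0])) < 2:
            raise ValueError("need at least 2 groups at the top level")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, value_col: str = "value", factor_cols=None
    ) -> "NestedAnova":
        """Build from long-form data (e.g. columns group, animal, cell, value)."""
        if factor_cols is None:
            factor_cols = [c for c in ("group", "animal", "cell") if c in df.columns]
        return cls(df[value_col].to_numpy(), [df[c].to_numpy() for c in factor_cols])

    # ------------------------------------------------------------------ fit
    def fit(self) -> NestedAnovaResults:
        y = self.y
        n_total = y.size
        grand = y.mean()
        L = len(self.paths)

        # per-level unit means/counts, as dicts keyed by path tuple
        unit_stats: list[dict] = []
        for lvl_paths in self.paths:
            d: dict = {}
            for p, v in zip(lvl_paths, y):
                if p in d:
                    d[p][0] += v
                    d[p][1] += 1
                else:
                    d[p] = [v, 1]
            unit_stats.append({p: (s / c, c) for p, (s, c) in d.items()})

        # hierarchical sums of squares and df
        ss = np.empty(L)
        df = np.empty(L, dtype=int)
        for l in range(L):
            total = 0.0
            for p, (mean, count) in unit_stats[l].items():
                parent_mean = grand if l == 0 else unit_stats[l - 1][p[:-1]][0]
                total += count * (mean - parent_mean) ** 2
            ss[l] = total
            df[l] = len(unit_stats[l]) - (1 if l == 0 else len(unit_stats[l - 1]))

        lowest = unit_stats[-1]
        lowest_means = np.array([lowest[p][0] for p in self.paths[-1]])
        ss_within = float(np.sum((y - lowest_means) ** 2))
        df_within = n_total - len(lowest)

        ms = np.array([s / d if d > 0 else np.nan for s, d in zip(ss, df)])
        ms_within = ss_within / df_within if df_within > 0 else np.nan

        # F: each level against the level nested immediately below
        f_vals = np.full(L, np.nan)
        p_vals = np.full(L, np.nan)
        for l in range(L):
            denom = ms[l + 1] if l + 1 < L else ms_within
            denom_df = df[l + 1] if l + 1 < L else df_within
            if df[l] > 0 and np.isfinite(denom) and denom > 0 and denom_df > 0:
                f_vals[l] = ms[l] / denom
                p_vals[l] = stats.f.sf(f_vals[l], df[l], denom_df)
            elif df[l] == 0:
                warnings.warn(
                    f"level {l} has a single unit per branch; untestable (missing)"
                )

        # expected-mean-square coefficients from the design counts:
        # coefficient of sigma2_k (k >= l) in E[SS_l] is C(l,k) - C(l-1,k),
        # C(l,k) = sum over level-l units u of (sum of n_v^2 over level-k
        # units v inside u) / n_u; C(-1,k) uses the whole data set as "u".
        def c_coef(l: int, k: int) -> float:
            sq = unit_stats[k]
            if l == -1:
                return sum(c * c for _, c in sq.values()) / n_total
            total = 0.0
            # group level-k squared counts by their level-l ancestor
            acc: dict = {}
            for p, (_, c) in sq.items():
                anc = p[: l + 1]
                acc[anc] = acc.get(anc, 0.0) + c * c
            for anc, s2 in acc.items():
                total += s2 / unit_stats[l][anc][1]
            return total

        coef = np.zeros((L, L))
        for l in range(L):
            for k in range(l, L):
                coef[l, k] = c_coef(l, k) - c_coef(l - 1, k)

        # method of moments, bottom-up
        sigma2 = np.zeros(L + 1)  # levels 0..L-1 then residual
        sigma2[L] = ms_within if np.isfinite(ms_within) else 0.0
        for l in range(L - 1, -1, -1):
            if df[l] <= 0 or coef[l, l] == 0:
                sigma2[l] = np.nan
                continue
            resid_part = df[l] * sigma2[L]
            nested_part = sum(
                coef[l, k] * sigma2[k]
                for k in range(l + 1, L)
                if np.isfinite(sigma2[k])
            )
            sigma2[l] = (ss[l] - resid_part - nested_part) / coef[l, l]

        clamped = np.where(np.isnan(sigma2), 0.0, np.clip(sigma2, 0.0, None))
        total_var = clamped.sum()
        percents = (
            100.0 * clamped / total_var if total_var > 0 else np.zeros(L + 1)
        )
        if total_var == 0:
            warnings.warn("all data identical; variance components degenerate")

        names = self.LEVEL_NAMES[:L] + ["within"]
        levels = []
        for l in range(L):
            levels.append(
                _LevelResult(
                    names[l], float(ss[l]), int(df[l]), float(ms[l]),
                    float(f_vals[l]), float(p_vals[l]),
                    float(sigma2[l]), float(clamped[l]), float(percents[l]),
                )
            )
        levels.append(
            _LevelResult(
                "within", ss_within, int(df_within), float(ms_within),
                float("nan"), float("nan"),
                float(sigma2[L]), float(clamped[L]), float(percents[L]),
            )
        )
        return NestedAnovaResults(self, levels)
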