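"""Rank tests against enumeration oracles; nested ANOVA against brute force."""

import itertools

import numpy as np
import pandas as pd
import pytest

from squant import NestedAnova, mann_whitney, wilcoxon_paired


# --------------------------------------------------------------------------
# enumeration oracles (independent of scipy)
# --------------------------------------------------------------------------

def mw_exact_oracle(x, y):
    """Two-sided exact Mann–Whitney p by enumerating all label assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    combined = np.concatenate([x, y])
    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    us = []
    for idx in itertools.combinations(range(nx + ny), nx):
        xs = combined[list(idx)]
        ys = np.delete(combined, list(idx))
        us.append(sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys))
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-12)
    p_ge = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


def wilcoxon_exact_oracle(x, y):
    """Two-sided exact signed-rank p by enumerating all sign patterns."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(ranks[np.array(signs, bool)].sum())
    ws = np.asarray(ws)
    w_min = min(w_obs, ranks.sum() - w_obs)
    p_le = np.mean(np.minimum(ws, ranks.sum() - ws) <= w_min + 1e-12)
    return min(1.0, p_le)


def nested_ss_oracle(df):
    """Brute-force hierarchical SS decomposition with explicit loops."""
    y = df["value"].to_numpy()
    grand = y.mean()
    ss = {}
    ss["group"] = 0.0
    for g, sub in df.groupby("group"):
        ss["group"] += len(sub) * (sub["value"].mean() - grand) ** 2
    ss["subgroup"] = 0.0
    for g, gsub in df.groupby("group"):
        gm = gsub["value"].mean()
        for a, asub in gsub.groupby("animal"):
            ss["subgroup"] += len(asub) * (asub["value"].mean() - gm) ** 2
    if "cell" in df.columns:
        ss["subsubgroup"] = 0.0
        for (g, a), asub in df.groupby(["group", "animal"]):
            am = asub["value"].mean()
            for c, csub in asub.groupby("cell"):
                ss["subsubgroup"] += len(csub) * (csub["value"].mean() - am) ** 2
        lowest = ["group", "animal", "cell"]
    else:
        lowest = ["group", "animal"]
    ss["within"] = 0.0
    for _, csub in df.groupby(lowest):
        cm = csub["value"].mean()
        ss["within"] += ((csub["value"] - cm) ** 2).sum()
    return ss


def random_unbalanced_design(rng, three_level=False):
    rows = []
    for g in range(int(rng.integers(2, 4))):
        for a in range(int(rng.integers(2, 5))):
            if three_level:
                for c in range(int(rng.integers(1, 4))):
                    for _ in range(int(rng.integers(2, 6))):
                        rows.append((f"g{g}", f"a{a}", f"c{c}", rng.normal()))
            else:
                for _ in range(int(rng.integers(2, 8))):
                    rows.append((f"g{g}", f"a{a}", None, rng.normal()))
    cols = ["group", "animal", "cell", "value"]
    df = pd.DataFrame(rows, columns=cols)
    return df if three_level else df.drop(columns="cell")


# --------------------------------------------------------------------------
# rank tests
# --------------------------------------------------------------------------

class TestMannWhitney:
    def test_identical_samples_p_one(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        # x=(1,2,3) vs y=(4,5,6): U=0, exact two-sided p = 2/20 = 0.1
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_agrees_with_enumeration_oracle(self, rng_factory):
        for seed in range(30):
            rng = rng_factory(seed)
            nx = int(rng.integers(2, 6))
            ny = int(rng.integers(2, 11 - nx))
            x = rng.normal(0, 1, nx)
            y = rng.normal(rng.normal(), 1, ny)
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(mw_exact_oracle(x, y), abs=1e-12)

    def test_large_sample_asymptotic_sanity(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        _, p = mann_whitney(x, y)
        assert p < 1e-10

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestWilcoxonPaired:
    def test_all_positive_diffs_n6(self):
        x = np.arange(6.0)
        y = x + 1.0
        w, p = wilcoxon_paired(y, x)
        assert p == pytest.approx(2 / 64)  # 0.03125

    def test_identical_pairs_p_one(self):
        x = np.arange(5.0)
        with pytest.warns(UserWarning, match="zero"):
            _, p = wilcoxon_paired(x, x)
        assert p == 1.0

    def test_agrees_with_enumeration_oracle(self, rng_factory):
        for seed in range(30):
            rng = rng_factory(100 + seed)
            n = int(rng.integers(5, 11))
            x = rng.normal(0, 1, n)
            y = x + rng.normal(0.3, 1, n)
            _, p = wilcoxon_paired(x, y)
            assert p == pytest.approx(wilcoxon_exact_oracle(x, y), abs=1e-12)

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1.0, 2.0], [1.0])


# --------------------------------------------------------------------------
# nested ANOVA
# --------------------------------------------------------------------------

class TestNestedAnova:
    def test_ss_df_match_bruteforce_on_unbalanced_designs(self, rng_factory):
        for seed in range(25):
            rng = rng_factory(seed)
            three = bool(seed % 2)
            df = random_unbalanced_design(rng, three_level=three)
            cols = ["group", "animal"] + (["cell"] if three else [])
            res = NestedAnova.from_dataframe(df, "value", cols).fit()
            oracle = nested_ss_oracle(df)
            t = res.table.set_index("source")
            for name, key in (
                ("group", "group"),
                ("subgroup", "subgroup"),
                ("subsubgroup", "subsubgroup"),
                ("within", "within"),
            ):
                if key in oracle:
                    assert t.loc[name, "ss"] == pytest.approx(
                        oracle[key], abs=1e-8, rel=1e-8
                    )
            assert t["df"].sum() == len(df) - 1

    def test_total_ss_additivity(self, rng):
        df = random_unbalanced_design(rng, three_level=True)
        res = NestedAnova.from_dataframe(df, "value", ["group", "animal", "cell"]).fit()
        total = ((df["value"] - df["value"].mean()) ** 2).sum()
        assert res.table["ss"].sum() == pytest.approx(total, rel=1e-9)

    def test_all_equal_data_degenerate_and_flagged(self):
        df = pd.DataFrame(
            {
                "group": np.repeat(["g0", "g1"], 15),
                "animal": np.tile(np.repeat(["a0", "a1", "a2"], 5), 2),
                "value": 3.0,
            }
        )
        with pytest.warns(UserWarning, match="identical"):
            res = NestedAnova.from_dataframe(df, "value", ["group", "animal"]).fit()
        assert res.table["ss"].sum() == 0.0

    def test_component_recovery_on_balanced_design(self, rng_factory):
        # generating model: group variance 0, subgroup variance 2, residual 1
        comps = []
        for seed in range(50):
            rng = rng_factory(seed)
            rows = []
            for g in range(2):
                for a in range(4):
                    u = rng.normal(0, np.sqrt(2))
                    for _ in range(5):
                        rows.append((g, a, u + rng.normal()))
            gg, aa, vv = map(np.array, zip(*rows))
            res = NestedAnova(vv, [gg, aa]).fit()
            comps.append([lv.var_component_raw for lv in res.levels])
        mean = np.mean(comps, axis=0)
        assert mean[1] == pytest.approx(2.0, rel=0.25)
        assert mean[2] == pytest.approx(1.0, rel=0.25)
        assert abs(mean[0]) < 0.5

    def test_percentages_sum_to_100(self, rng):
        df = random_unbalanced_design(rng, three_level=True)
        res = NestedAnova.from_dataframe(df, "value", ["group", "animal", "cell"]).fit()
        assert res.variance_components["percent_of_total"].sum() == pytest.approx(
            100.0, abs=0.01
        )

    def test_null_type_i_rate_smoke(self, rng_factory):
        # small smoke version; the full 2000-replicate calibration runs in
        # the acceptance suite
        hits = 0
        n = 300
        rng = rng_factory(7)
        for _ in range(n):
            rows = []
            for g in range(2):
                for a in range(4):
                    u = rng.normal()
                    for _ in range(5):
                        rows.append((g, a, u + rng.normal()))
            gg, aa, vv = map(np.array, zip(*rows))
            res = NestedAnova(vv, [gg, aa]).fit()
            hits += res.levels[0].p < 0.05
        assert 0.01 < hits / n < 0.10

    def test_single_unit_level_untestable(self):
        df = pd.DataFrame(
            {
                "group": np.repeat(["g0", "g1"], 6),
                "animal": np.repeat(["a0", "a1"], 6),  # one animal per group
                "value": np.arange(12.0),
            }
        )
        with pytest.warns(UserWarning, match="untestable"):
            res = NestedAnova.from_dataframe(df, "value", ["group", "animal"]).fit()
        t = res.table.set_index("source")
        assert t.loc["subgroup", "df"] == 0
        assert np.isnan(t.loc["subgroup", "p"])

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            NestedAnova(np.arange(6.0), [np.repeat("g0", 6), np.tile(["a", "b"], 3)])
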