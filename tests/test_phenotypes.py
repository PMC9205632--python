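"""Phenotype preparation: proportions on the gating hierarchy, the
rank-based inverse normal transform, log2 cytokines, the covariate screen
and the cell x cytokine correlation map."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from immunoqtl import (
    correlate_cells_cytokines,
    covariate_screen,
    derive_proportions,
    inverse_rank_transform,
    log2_transform,
)


@pytest.fixture()
def toy_hierarchy():
    return pd.DataFrame(
        {
            "node": ["root", "T", "B", "T_sub"],
            "parent": [None, "root", "root", "T"],
            "category": ["root", "T", "B", "T"],
        }
    )


class TestProportions:
    def test_child_over_parent(self, toy_hierarchy):
        counts = pd.DataFrame(
            {"root": [100.0], "T": [60.0], "B": [30.0], "T_sub": [30.0]},
            index=["s1"],
        )
        tt = derive_proportions(counts, toy_hierarchy)
        assert tt.values.loc["s1", "T"] == pytest.approx(0.6)
        assert tt.values.loc["s1", "T_sub"] == pytest.approx(0.5)
        assert tt.meta.loc["T_sub", "parent"] == "T"
        assert tt.meta.loc["T_sub", "grandparent"] == "root"

    def test_zero_parent_gives_missing(self, toy_hierarchy):
        counts = pd.DataFrame(
            {"root": [100.0], "T": [0.0], "B": [30.0], "T_sub": [0.0]},
            index=["s1"],
        )
        tt = derive_proportions(counts, toy_hierarchy)
        assert np.isnan(tt.values.loc["s1", "T_sub"])

    def test_full_sibling_set_sums_to_one(self):
        hier = pd.DataFrame(
            {
                "node": ["p", "a", "b", "c"],
                "parent": [None, "p", "p", "p"],
                "category": ["root", "T", "T", "T"],
            }
        )
        counts = pd.DataFrame(
            {"p": [60.0], "a": [30.0], "b": [20.0], "c": [10.0]}, index=["s"]
        )
        tt = derive_proportions(counts, hier)
        assert tt.values.loc["s", ["a", "b", "c"]].sum() == pytest.approx(1.0)

    def test_missing_node_named_in_error(self, toy_hierarchy):
        counts = pd.DataFrame({"root": [1.0], "T": [1.0], "B": [1.0]}, index=["s"])
        with pytest.raises(ValueError, match="T_sub"):
            derive_proportions(counts, toy_hierarchy)

    def test_scale_invariance(self, toy_hierarchy, rng):
        counts = pd.DataFrame(
            rng.uniform(10, 100, size=(5, 4)),
            columns=["root", "T", "B", "T_sub"],
            index=[f"s{i}" for i in range(5)],
        )
        a = derive_proportions(counts, toy_hierarchy).values
        b = derive_proportions(counts * 7.3, toy_hierarchy).values
        pd.testing.assert_frame_equal(a, b)


class TestInverseRank:
    def test_middle_of_three_is_zero(self):
        z = inverse_rank_transform([5, 1, 9])
        assert z[0] == pytest.approx(0.0, abs=1e-12)

    def test_blom_maximum_for_n3(self):
        z = inverse_rank_transform([5, 1, 9])
        # Phi^-1((3 - 0.375) / 3.25)
        assert z[2] == pytest.approx(stats.norm.ppf(0.80769, 0, 1), abs=1e-4)
        assert z[2] == pytest.approx(0.8694, abs=1e-4)

    def test_mean_and_skewness_near_zero(self, rng):
        z = inverse_rank_transform(rng.uniform(size=501))
        assert abs(z.mean()) < 1e-6
        assert abs(stats.skew(z)) < 1e-6

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            inverse_rank_transform([2.0, 2.0, 2.0])

    def test_missing_stays_missing(self):
        z = inverse_rank_transform([1.0, np.nan, 3.0, 2.0])
        assert np.isnan(z[1]) and not np.isnan(z[[0, 2, 3]]).any()

    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=4, max_size=40, unique=True
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_monotone_transform(self, values):
        # scaling by a power of two is strictly monotone and float-exact,
        # so it must preserve ranks and hence the transform output
        v = np.asarray(values)
        np.testing.assert_allclose(
            inverse_rank_transform(v), inverse_rank_transform(v * 8.0)
        )
        order = np.argsort(np.argsort(v))
        np.testing.assert_allclose(
            inverse_rank_transform(v),
            inverse_rank_transform(order.astype(float)),
        )


class TestLog2:
    def test_elementwise(self):
        df = pd.DataFrame({"c": [8.0, 1.0]}, index=["a", "b"])
        tt = log2_transform(df)
        assert tt.values["c"].tolist() == [3.0, 0.0]
        assert tt.meta.loc["c", "trait_class"] == "cytokine"

    def test_nonpositive_rejected_with_location(self):
        df = pd.DataFrame({"c": [8.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match=r"\(b, c\)"):
            log2_transform(df)

    def test_stimulation_parsed_from_name(self):
        df = pd.DataFrame({"IL6_LPS": [2.0, 4.0]}, index=["a", "b"])
        assert log2_transform(df).meta.loc["IL6_LPS", "stimulation"] == "LPS"


class TestCovariateScreen:
    def _cov(self, n, rng):
        return pd.DataFrame(
            {
                "age": rng.uniform(20, 70, n),
                "sex": rng.integers(0, 2, n).astype(float),
                "day": rng.integers(1, 366, n).astype(float),
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_exact_age_dependence_detected(self, rng):
        cov = self._cov(80, rng)
        traits = pd.DataFrame({"y": 2 * cov["age"] + 1}, index=cov.index)
        res = covariate_screen(traits, cov)
        age = res.set_index(["trait", "covariate"]).loc[("y", "age")]
        assert age["statistic"] == pytest.approx(1.0)
        assert age["q"] < 1e-10

    def test_seasonal_trait_detected(self, rng):
        cov = self._cov(200, rng)
        y = np.sin(2 * np.pi * cov["day"] / 365) + rng.normal(0, 0.1, 200)
        res = covariate_screen(pd.DataFrame({"y": y}, index=cov.index), cov)
        sea = res.set_index(["trait", "covariate"]).loc[("y", "season")]
        assert sea["q"] < 1e-6

    def test_insufficient_pairs_skipped(self, rng):
        cov = self._cov(30, rng)
        y = np.full(30, np.nan)
        y[:5] = rng.normal(size=5)
        traits = pd.DataFrame({"sparse": y, "full": rng.normal(size=30)}, index=cov.index)
        res = covariate_screen(traits, cov)
        assert "sparse" not in set(res["trait"])
        assert "full" in set(res["trait"])

    def test_bh_false_positive_control(self, rng):
        # global null: expected fraction of q<0.05 flags is at most ~5%
        flagged = []
        for rep in range(10):
            n = 60
            cov = self._cov(n, rng)
            traits = pd.DataFrame(
                rng.normal(size=(n, 50)),
                columns=[f"t{i}" for i in range(50)],
                index=cov.index,
            )
            res = covariate_screen(traits, cov)
            flagged.append(res["significant"].mean())
        assert np.mean(flagged) <= 0.05

    def test_q_at_least_p_and_monotone(self, rng):
        cov = self._cov(100, rng)
        traits = pd.DataFrame(
            rng.normal(size=(100, 20)),
            columns=[f"t{i}" for i in range(20)],
            index=cov.index,
        )
        res = covariate_screen(traits, cov).dropna(subset=["p"])
        assert (res["q"] >= res["p"] - 1e-12).all()
        for _, grp in res.groupby("covariate"):
            g = grp.sort_values("p")
            assert (np.diff(g["q"]) >= -1e-12).all()


class TestCellCytokineMap:
    def test_rank_duplicate_gives_rho_one(self, rng):
        n = 30
        cells = pd.DataFrame({"c": rng.uniform(size=n)}, index=range(n))
        cyt = pd.DataFrame({"k": cells["c"] ** 3}, index=range(n))  # same ranks
        res = correlate_cells_cytokines(cells, cyt)
        assert res["rho"].iloc[0] == pytest.approx(1.0)

    def test_negated_ranks_give_minus_one(self, rng):
        n = 30
        cells = pd.DataFrame({"c": rng.uniform(size=n)}, index=range(n))
        cyt = pd.DataFrame({"k": -cells["c"]}, index=range(n))
        res = correlate_cells_cytokines(cells, cyt)
        assert res["rho"].iloc[0] == pytest.approx(-1.0)

    def test_matches_scipy_spearman(self, rng):
        n = 40
        cells = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        cyt = pd.DataFrame(rng.normal(size=(n, 2)), columns=list("xy"))
        res = correlate_cells_cytokines(cells, cyt).set_index(["cell", "cytokine"])
        for c in "abc":
            for k in "xy":
                rho, p = stats.spearmanr(cells[c], cyt[k])
                assert res.loc[(c, k), "rho"] == pytest.approx(rho, abs=1e-10)
                assert res.loc[(c, k), "p"] == pytest.approx(p, rel=1e-6)

    def test_null_fdr_control(self, rng):
        fracs = []
        for rep in range(10):
            n = 50
            cells = pd.DataFrame(rng.normal(size=(n, 25)))
            cyt = pd.DataFrame(rng.normal(size=(n, 10)))
            res = correlate_cells_cytokines(cells, cyt)
            fracs.append(res["significant"].mean())
        assert np.mean(fracs) <= 0.05

    def test_disjoint_samples_rejected(self):
        cells = pd.DataFrame({"c": [1.0]}, index=["a"])
        cyt = pd.DataFrame({"k": [1.0]}, index=["b"])
        with pytest.raises(ValueError):
            correlate_cells_cytokines(cells, cyt)
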