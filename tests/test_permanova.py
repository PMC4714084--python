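"""PERMANOVA: df arithmetic for crossed/nested mixed designs, SS
conservation, the classical-ANOVA oracle, exact permutation enumeration,
pairwise t-tests and FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wingmorph import permanova
from wingmorph.permanova import Design, Factor, Term, UnbalancedDesignError

REPLICATE_FORMULA = (
    "sex + wing + image(wing) + measure(image*wing) "
    "+ sex:wing + sex:image(wing) + sex:measure(image*wing)"
)


@pytest.fixture(scope="module")
def replicate_design():
    return Design.from_formula(REPLICATE_FORMULA, random=("image", "measure"))


class TestDesignDf:
    def test_measurement_error_design_dfs(self, replicate_design):
        # sex 2 × wing 2, image 2-in-wing, measure 2-in-(image×wing),
        # 7 replicate specimens per sex cell → N = 112
        dfs = permanova.design_df(
            replicate_design,
            {"sex": 2, "wing": 2, "image": 2, "measure": 2},
            replicates=7,
        )
        assert dfs == {
            "sex": 1,
            "wing": 1,
            "image(wing)": 2,
            "measure(image*wing)": 4,
            "sex:wing": 1,
            "sex:image(wing)": 2,
            "sex:measure(image*wing)": 4,
            "Residual": 96,
        }

    def test_one_way_textbook_case(self):
        dfs = permanova.design_df(
            permanova.one_way_design("group"), {"group": 2}, replicates=3
        )
        assert dfs == {"group": 1, "Residual": 4}

    def test_balanced_subsets_reproduce_one_way_dfs(self):
        # the balanced one-way layouts used for the species/cluster tests
        design = permanova.one_way_design("g")
        for levels, reps, expected in [
            (3, 31, {"g": 2, "Residual": 90}),
            (3, 19, {"g": 2, "Residual": 54}),
            (5, 10, {"g": 4, "Residual": 45}),
            (5, 3, {"g": 4, "Residual": 10}),
        ]:
            assert permanova.design_df(design, {"g": levels}, reps) == expected

    def test_cyclic_nesting_rejected(self):
        with pytest.raises(ValueError, match="cyclic"):
            Design(
                factors={
                    "a": Factor("a", nested_in=("b",)),
                    "b": Factor("b", nested_in=("a",)),
                },
                terms=[Term(("a",))],
            )


class TestPermanova:
    def test_univariate_one_way_equals_classical_anova(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.standard_normal(24)
            labels = np.repeat(["a", "b", "c"], 8)
            table = permanova.one_way_permanova(y, labels, n_perm=0)
            f_classical = stats.f_oneway(y[:8], y[8:16], y[16:]).statistic
            assert table.loc["group", "F"] == pytest.approx(f_classical, abs=1e-10)

    def test_ss_conservation(self, replicate_design):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((112, 6))
        meta = pd.DataFrame(
            [
                {"sex": s, "wing": w, "image": i, "measure": m, "rep": r}
                for s in "MF"
                for w in "RL"
                for i in "12"
                for m in "AB"
                for r in range(7)
            ]
        )
        table = permanova.permanova(x, replicate_design, meta, n_perm=0)
        terms = table.drop(index="Total")
        assert terms["SS"].sum() == pytest.approx(
            table.loc["Total", "SS"], rel=1e-8
        )
        assert terms["df"].sum() == table.loc["Total", "df"]

    def test_identical_observations_zero_between_ss(self):
        x = np.tile([1.0, 2.0], (12, 1))
        table = permanova.one_way_permanova(x, np.repeat(["a", "b"], 6), n_perm=0)
        assert table.loc["group", "SS"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_enumeration_matches_brute_force_tail(self):
        # tiny 2×3 one-way dataset: enumerate all 6! row permutations and
        # compare with an independent scipy-based enumeration over the 20
        # distinct group splits
        rng = np.random.default_rng(2)
        y = rng.standard_normal(6)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        table = permanova.one_way_permanova(y, labels, exact=True)
        f_obs = stats.f_oneway(y[:3], y[3:]).statistic
        exceed = total = 0
        for combo in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in combo]
            f = stats.f_oneway(y[list(combo)], y[rest]).statistic
            total += 1
            exceed += f >= f_obs - 1e-12
        assert table.loc["group", "p_perm"] == pytest.approx(exceed / total, abs=1e-12)

    def test_permutation_p_reproducible_and_bounded(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((18, 4))
        labels = np.repeat(["a", "b", "c"], 6)
        t1 = permanova.one_way_permanova(x, labels, n_perm=499, seed=11)
        t2 = permanova.one_way_permanova(x, labels, n_perm=499, seed=11)
        p = t1.loc["group", "p_perm"]
        assert p == t2.loc["group", "p_perm"]
        assert 1 / 500 <= p <= 1.0

    def test_unbalanced_multifactor_rejected(self):
        rng = np.random.default_rng(4)
        design = Design.from_formula("a + b + a:b")
        meta = pd.DataFrame(
            {"a": ["x"] * 5 + ["y"] * 3, "b": ["u", "v"] * 4}
        )
        with pytest.raises(UnbalancedDesignError, match="balanced_subsample"):
            permanova.permanova(rng.standard_normal((8, 2)), design, meta, n_perm=0)

    def test_ems_denominators_for_mixed_nested_design(self, replicate_design):
        denoms = permanova._select_denominators(replicate_design)
        by_label = {
            t.label(replicate_design): (
                d if d == "Residual" else d.label(replicate_design),
                quasi,
            )
            for t, (d, quasi) in denoms.items()
        }
        assert by_label == {
            "sex": ("Residual", False),
            "wing": ("image(wing)", False),
            "image(wing)": ("measure(image*wing)", False),
            "measure(image*wing)": ("Residual", False),
            "sex:wing": ("sex:image(wing)", False),
            "sex:image(wing)": ("sex:measure(image*wing)", False),
            "sex:measure(image*wing)": ("Residual", False),
        }


class TestPairwise:
    def test_two_group_t_squared_equals_pair_f(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((20, 3))
        labels = np.repeat(["a", "b"], 10)
        pw = permanova.pairwise_tests(x, labels, n_perm=99, seed=1)
        f = permanova.one_way_permanova(x, labels, n_perm=0).loc["group", "F"]
        assert pw.loc[0, "t"] ** 2 == pytest.approx(f, abs=1e-10)

    def test_shifted_group_has_largest_t(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((30, 4))
        x[20:] += 6.0
        labels = np.repeat(["a", "b", "far"], 10)
        pw = permanova.pairwise_tests(x, labels, n_perm=0).set_index(
            ["group_1", "group_2"]
        )
        t_ab = pw.loc[("a", "b"), "t"]
        assert pw.loc[("a", "far"), "t"] > t_ab
        assert pw.loc[("b", "far"), "t"] > t_ab

    def test_null_data_rarely_significant_after_fdr(self):
        rng = np.random.default_rng(7)
        n_sig = 0
        n_sim = 40
        for i in range(n_sim):
            x = rng.standard_normal((18, 3))
            labels = np.repeat(["a", "b", "c"], 6)
            pw = permanova.pairwise_tests(x, labels, n_perm=199,
                                          seed=int(rng.integers(2**31)))
            n_sig += (pw["p_fdr"] < 0.05).any()
        assert n_sig / n_sim <= 0.15  # ~5% expected familywise under the null

    def test_tiny_pair_flagged_untestable(self):
        x = np.random.default_rng(8).standard_normal((5, 2))
        labels = ["a", "a", "b", "b", "c"]
        pw = permanova.pairwise_tests(x, labels, n_perm=49, seed=2)
        row = pw[(pw["group_1"] == "a") & (pw["group_2"] == "c")].iloc[0]
        assert not row["testable"] and np.isnan(row["t"])


class TestFdr:
    def test_hand_enumerated_step_up(self):
        # q_i = min_{j≥i} p_(j)·m/j: (0.01,0.02,0.04) → (0.03,0.03,0.04)
        assert np.allclose(
            permanova.fdr_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_and_tied_values_unchanged(self):
        assert permanova.fdr_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(permanova.fdr_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.001, 1, 20)
        q = permanova.fdr_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1)
        # preserves the order of evidence (up to ties introduced by step-up)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            permanova.fdr_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            permanova.fdr_adjust([1.5])


class TestBalancedSubsample:
    @pytest.fixture
    def meta(self, cohort_dataset):
        return cohort_dataset.meta

    def test_exact_counts_and_determinism(self, meta):
        ids1 = permanova.balanced_subsample(meta, "morphospecies", 31, seed=5)
        ids2 = permanova.balanced_subsample(meta, "morphospecies", 31, seed=5)
        assert ids1 == ids2
        counts = meta.loc[ids1, "morphospecies"].value_counts()
        assert set(counts) == {31}

    def test_minimum_group_returned_whole(self, meta):
        males = meta[meta.sex == "male"]
        n_min = males["genotypic_cluster"].value_counts().min()
        ids = permanova.balanced_subsample(males, "genotypic_cluster", n_min, seed=1)
        smallest = males["genotypic_cluster"].value_counts().idxmin()
        assert set(males[males.genotypic_cluster == smallest].index) <= set(ids)

    def test_oversized_request_names_group(self, meta):
        with pytest.raises(ValueError, match="rosa"):
            permanova.balanced_subsample(meta, "morphospecies", 51, seed=1)
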