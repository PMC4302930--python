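import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from derepressome.annotation import GeneModel, GenomeAnnotation
from derepressome.expression import (
    CountMatrix,
    DiffratPermutationTest,
    ExpressionParams,
    call_differential,
    compute_fpkm,
    condition_means,
    diffrat_score,
)


def annotation_with_lengths(lengths: dict[str, int]) -> GenomeAnnotation:
    genes = []
    pos = 1000
    for gene_id, length in lengths.items():
        genes.append(
            GeneModel(gene_id, "chr1", pos, pos + length, "+", ((pos, pos + length),))
        )
        pos += length + 5000
    return GenomeAnnotation(genes)


class TestFpkm:
    def test_definition(self):
        ann = annotation_with_lengths({"g": 1000})
        cm = CountMatrix(
            pd.DataFrame({"s1": [10]}, index=["g"]),
            pd.Series({"s1": 1_000_000}),
        )
        assert compute_fpkm(cm, ann).loc["g", "s1"] == pytest.approx(10.0)

    def test_zero_counts_give_zero(self):
        ann = annotation_with_lengths({"g": 500})
        cm = CountMatrix(pd.DataFrame({"s1": [0]}, index=["g"]), pd.Series({"s1": 2e6}))
        assert compute_fpkm(cm, ann).loc["g", "s1"] == 0.0

    def test_scale_invariance_under_joint_doubling(self):
        ann = annotation_with_lengths({"g1": 1200, "g2": 800})
        counts = pd.DataFrame({"s1": [7, 31], "s2": [3, 12]}, index=["g1", "g2"])
        lib = pd.Series({"s1": 5e6, "s2": 4e6})
        base = compute_fpkm(CountMatrix(counts, lib), ann)
        doubled = compute_fpkm(CountMatrix(counts * 2, lib * 2), ann)
        pd.testing.assert_frame_equal(base, doubled)

    def test_missing_gene_reported_by_id(self):
        ann = annotation_with_lengths({"g1": 1000})
        cm = CountMatrix(
            pd.DataFrame({"s1": [1, 2]}, index=["g1", "ghost"]), pd.Series({"s1": 1e6})
        )
        with pytest.raises(KeyError, match="ghost"):
            compute_fpkm(cm, ann)

    def test_zero_library_size_rejected(self):
        with pytest.raises(ValueError, match="library"):
            CountMatrix(pd.DataFrame({"s1": [1]}, index=["g"]), pd.Series({"s1": 0}))


class TestConditionMeans:
    def test_means_and_order_invariance(self):
        fpkm = pd.DataFrame(
            {"c1": [1.0], "c2": [3.0], "m1": [2.0], "m2": [4.0]}, index=["g"]
        )
        design = pd.Series(
            {"c1": "control", "c2": "control", "m1": "mutant", "m2": "mutant"}
        )
        out = condition_means(fpkm, design)
        assert out.loc["g", "a"] == 3.0  # mutant
        assert out.loc["g", "b"] == 2.0  # control
        shuffled = condition_means(fpkm[["m2", "c1", "m1", "c2"]], design)
        pd.testing.assert_frame_equal(out, shuffled)

    def test_single_sample_condition_equals_that_sample(self):
        fpkm = pd.DataFrame({"c1": [5.0], "m1": [9.0]}, index=["g"])
        design = pd.Series({"c1": "control", "m1": "mutant"})
        out = condition_means(fpkm, design)
        assert out.loc["g", "a"] == 9.0 and out.loc["g", "b"] == 5.0

    def test_unknown_condition_label_rejected(self):
        fpkm = pd.DataFrame({"s": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="unknown condition"):
            condition_means(fpkm, pd.Series({"s": "treated"}))


class TestDiffrat:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (5.0, 5.0, 0.0),
            (3.0, 0.0, 6.0),       # 3 * log2(4/1)
            (0.0, 3.0, -6.0),
            (7.0, 1.0, 12.0),      # 6 * log2(8/2)
        ],
    )
    def test_hand_evaluated_values(self, a, b, expected):
        assert diffrat_score(a, b) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            diffrat_score(-1.0, 2.0)

    # values below ~1e-12 underflow the +1 pseudocount in double precision,
    # so strict sign claims are only representable above that floor
    @settings(max_examples=300, derandomize=True)
    @given(
        a=st.one_of(st.just(0.0), st.floats(1e-9, 1e4, allow_nan=False)),
        b=st.one_of(st.just(0.0), st.floats(1e-9, 1e4, allow_nan=False)),
    )
    def test_antisymmetry_and_sign(self, a, b):
        forward, backward = diffrat_score(a, b), diffrat_score(b, a)
        assert forward == pytest.approx(-backward, abs=1e-9)
        if a > b:
            assert forward > 0
        elif a == b:
            assert forward == 0.0

    def test_strictly_increasing_in_a_above_b(self):
        b = 2.0
        grid = np.linspace(2.001, 500.0, 400)
        values = diffrat_score(grid, np.full_like(grid, b))
        assert (np.diff(values) > 0).all()


def per_gene_enumeration_oracle(fpkm: pd.DataFrame, design: pd.Series) -> np.ndarray:
    """Brute-force per-gene permutation p on |diffrat|, independent route."""

    def raw_diffrat(a, b):
        return abs(a - b) * math.log2((a + 1) / (b + 1))

    samples = list(fpkm.columns)
    n_mut = (design == "mutant").sum()
    mut_obs = set(design.index[design == "mutant"])
    p_values = []
    for _, row in fpkm.iterrows():
        def stat(mut_set):
            a = np.mean([row[s] for s in mut_set])
            b = np.mean([row[s] for s in samples if s not in mut_set])
            return abs(raw_diffrat(a, b))

        observed = stat(mut_obs)
        null = [stat(set(c)) for c in combinations(samples, n_mut)]
        p_values.append(sum(v >= observed - 1e-12 for v in null) / len(null))
    return np.array(p_values)


class TestPerGenePermutation:
    def random_instance(self, seed, n_genes=12, n_ctrl=3, n_mut=3):
        rng = np.random.default_rng(seed)
        samples = [f"c{i}" for i in range(n_ctrl)] + [f"m{i}" for i in range(n_mut)]
        fpkm = pd.DataFrame(
            rng.gamma(2.0, 3.0, size=(n_genes, len(samples))), columns=samples,
            index=[f"g{i}" for i in range(n_genes)],
        )
        design = pd.Series(["control"] * n_ctrl + ["mutant"] * n_mut, index=samples)
        return fpkm, design

    @pytest.mark.parametrize("n_ctrl,n_mut", [(2, 2), (3, 3), (3, 4), (5, 5)])
    def test_matches_enumeration_oracle(self, n_ctrl, n_mut):
        fpkm, design = self.random_instance(seed=n_ctrl * 10 + n_mut,
                                            n_ctrl=n_ctrl, n_mut=n_mut)
        test = DiffratPermutationTest(method="per-gene").fit(fpkm, design)
        expected = per_gene_enumeration_oracle(fpkm, design)
        assert test.exhaustive_
        np.testing.assert_allclose(test.results_["p_raw"].to_numpy(), expected)

    def test_spiked_gene_attains_the_minimal_achievable_p(self):
        fpkm, design = self.random_instance(seed=1, n_genes=30)
        fpkm.iloc[0] = [0.0, 0.0, 0.0, 100.0, 100.0, 100.0]
        test = DiffratPermutationTest(method="per-gene").fit(fpkm, design)
        # 20 balanced splits; the observed one and its mirror are the extremes
        assert test.results_["p_raw"].iloc[0] == pytest.approx(2 / 20)
        assert test.results_["p_raw"].min() >= 2 / 20

    def test_all_constant_genes_get_p_one(self):
        fpkm, design = self.random_instance(seed=2)
        fpkm.iloc[:, :] = 7.5
        for method in ("per-gene", "pooled"):
            test = DiffratPermutationTest(method=method).fit(fpkm, design)
            assert (test.results_["p_adj"] == 1.0).all()
            assert (test.results_["status"] == "ns").all()

    def test_sampled_null_is_deterministic_and_valid(self):
        fpkm, design = self.random_instance(seed=3, n_ctrl=8, n_mut=8)
        first = DiffratPermutationTest(
            method="per-gene", n_permutations=400, random_state=5
        ).fit(fpkm, design)
        second = DiffratPermutationTest(
            method="per-gene", n_permutations=400, random_state=5
        ).fit(fpkm, design)
        assert not first.exhaustive_
        pd.testing.assert_frame_equal(first.results_, second.results_)
        p = first.results_["p_raw"]
        assert ((p > 0) & (p <= 1)).all()

    def test_too_few_replicates_rejected(self):
        fpkm, design = self.random_instance(seed=4, n_ctrl=1, n_mut=3)
        with pytest.raises(ValueError, match="replicates"):
            DiffratPermutationTest().fit(fpkm, design)

    def test_bh_adjustment_is_monotone_in_rank(self):
        fpkm, design = self.random_instance(seed=6, n_genes=40)
        res = DiffratPermutationTest(method="per-gene").fit(fpkm, design).results_
        ordered = res.sort_values("p_raw")
        assert (ordered["p_adj"].diff().dropna() >= -1e-12).all()
        assert ((res["p_raw"] > 0) & (res["p_raw"] <= 1)).all()


class TestPooledPermutation:
    def test_deterministic_at_fixed_seed(self, small_study):
        from derepressome.expression import differential_expression

        first = differential_expression(
            small_study["counts"], small_study["design"], small_study["annotation"]
        )
        second = differential_expression(
            small_study["counts"], small_study["design"], small_study["annotation"]
        )
        pd.testing.assert_frame_equal(first, second)

    def test_unbalanced_design_supported(self):
        rng = np.random.default_rng(9)
        samples = [f"c{i}" for i in range(3)] + [f"m{i}" for i in range(4)]
        fpkm = pd.DataFrame(rng.gamma(2.0, 3.0, size=(25, 7)), columns=samples)
        design = pd.Series(["control"] * 3 + ["mutant"] * 4, index=samples)
        test = DiffratPermutationTest(method="pooled").fit(fpkm, design)
        p = test.results_["p_raw"]
        assert ((p > 0) & (p <= 1)).all()


class TestCallDifferential:
    @pytest.mark.parametrize(
        "p_adj, diffrat, expected",
        [(0.009, 4.0, "up"), (0.011, 4.0, "ns"), (0.005, -2.0, "down")],
    )
    def test_threshold_logic(self, p_adj, diffrat, expected):
        table = pd.DataFrame({"diffrat": [diffrat], "p_adj": [p_adj]}, index=["g"])
        out = call_differential(table, ExpressionParams(alpha=0.01))
        assert out.loc["g", "status"] == expected

    def test_unfilled_p_adj_rejected(self):
        table = pd.DataFrame({"diffrat": [1.0], "p_adj": [np.nan]}, index=["g"])
        with pytest.raises(ValueError, match="p_adj"):
            call_differential(table)
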