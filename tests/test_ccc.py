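import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrcomm.ccc import (
    CCCConfig,
    detection_fraction,
    interaction_score,
    mean_expression_by_celltype,
    per_pair_permutation_null,
    permutation_pvalue,
    run_ccc,
    shared_permutation_null,
    summarize_celltypes,
    summarize_pathways,
)
from lrcomm.knowledgebase import Knowledgebase, LRPair

from conftest import make_dataset, default_cfg


class TestInteractionScore:
    @pytest.mark.parametrize(
        "ml,mr,expected",
        [
            (0.0, 5.0, 0.0),
            (5.0, 0.0, 0.0),
            (1.0, 1.0, math.log(2)),
            (2.0, 3.0, math.log(7)),
        ],
    )
    def test_closed_forms(self, ml, mr, expected):
        assert interaction_score(ml, mr) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            interaction_score(-0.1, 1.0)

    @given(
        x=st.floats(0.01, 100), y=st.floats(0.01, 100), d=st.floats(0.01, 10)
    )
    @settings(deadline=None, max_examples=50)
    def test_strictly_increasing_each_argument(self, x, y, d):
        assert interaction_score(x + d, y) > interaction_score(x, y)
        assert interaction_score(x, y + d) > interaction_score(x, y)


class TestMeansAndDetection:
    def test_mean_includes_zeros(self):
        ds = make_dataset([[0.0], [2.0]], ["A", "A"], ["g"])
        assert mean_expression_by_celltype(ds, ["g"]).loc["A", "g"] == 1.0

    def test_all_zero_gene(self):
        ds = make_dataset(np.zeros((4, 1)), ["A", "A", "B", "B"], ["g"])
        assert (mean_expression_by_celltype(ds, ["g"])["g"] == 0).all()

    def test_brute_force_three_types(self):
        rng = np.random.default_rng(3)
        mat = rng.random((12, 2))
        types = ["A", "B", "C"] * 4
        ds = make_dataset(mat, types, ["g1", "g2"])
        means = mean_expression_by_celltype(ds, ["g1", "g2"])
        for t in "ABC":
            rows = [i for i, ty in enumerate(types) if ty == t]
            for j, g in enumerate(["g1", "g2"]):
                assert means.loc[t, g] == pytest.approx(
                    sum(mat[i, j] for i in rows) / len(rows)
                )

    def test_detection_fraction_counting(self):
        mat = np.zeros((10, 1))
        mat[0, 0] = 1.5
        ds = make_dataset(mat, ["A"] * 10, ["g"])
        assert detection_fraction(ds, "g", "A") == pytest.approx(0.1)

    def test_detection_all_nonzero(self):
        ds = make_dataset(np.ones((5, 1)), ["A"] * 5, ["g"])
        assert detection_fraction(ds, "g", "A") == 1.0

    def test_unknown_gene_and_type(self):
        ds = make_dataset(np.ones((2, 1)), ["A", "B"], ["g"])
        with pytest.raises(KeyError):
            detection_fraction(ds, "nope", "A")
        with pytest.raises(ValueError):
            detection_fraction(ds, "g", "Z")


class TestPermutationPvalue:
    def test_observed_above_all_999(self):
        assert permutation_pvalue(10.0, np.arange(999) / 1000) == pytest.approx(0.001)

    def test_observed_below_all(self):
        assert permutation_pvalue(-1.0, np.arange(999) / 1000) == 1.0

    def test_counting_example(self):
        # 999 nulls, observed exceeds 950 of them -> 49 at or above
        nulls = np.concatenate([np.full(950, 0.0), np.full(49, 2.0)])
        assert permutation_pvalue(1.0, nulls) == pytest.approx(0.05)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue(1.0, [])


class TestSharedNull:
    def test_identity_permutation_reproduces_observed(
        self, planted_two_type_ds, one_pair_kb
    ):
        ds = planted_two_type_ds
        identity = np.tile(ds.cell_type, (1, 1))
        null = shared_permutation_null(
            ds, one_pair_kb, default_cfg(), permutations=identity
        )
        run = run_ccc(ds, one_pair_kb, default_cfg())
        obs = run.table.sort_values(["sender", "receiver"])["score"].to_numpy()
        got = null.scores[0].reshape(-1)  # (N, N, 1) flattened, types sorted
        np.testing.assert_allclose(np.sort(got), np.sort(obs))

    def test_identity_null_gives_p_one_everywhere(
        self, planted_two_type_ds, one_pair_kb
    ):
        ds = planted_two_type_ds
        identity = np.tile(ds.cell_type, (1, 1))
        null = shared_permutation_null(
            ds, one_pair_kb, default_cfg(), permutations=identity
        )
        run = run_ccc(ds, one_pair_kb, default_cfg(), null=null)
        assert (run.table["p_value"] == 1.0).all()

    def test_fixed_seed_determinism(self, small_ds, toy_kb):
        cfg = default_cfg(n_permutations=20, seed=42)
        a = shared_permutation_null(small_ds, toy_kb, cfg)
        b = shared_permutation_null(small_ds, toy_kb, cfg)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_exhaustive_matches_brute_force_enumeration(self):
        # 4 cells, 2 types (2+2): 4!/(2!2!)=6 distinct assignments
        mat = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 3.0], [0.0, 4.0]])
        labels = ["A", "A", "B", "B"]
        ds = make_dataset(mat, labels, ["lig", "rec"])
        kb = Knowledgebase(pairs=[LRPair("lig", "rec", "toy", "high")])
        null = shared_permutation_null(ds, kb, default_cfg(), exhaustive=True)
        assert null.scores.shape[0] == 6

        # independent oracle: enumerate label assignments with itertools
        expected = set()
        for perm in set(itertools.permutations(labels)):
            perm = list(perm)
            scores = []
            for s, r in itertools.product("AB", repeat=2):
                ml = np.mean([mat[i, 0] for i in range(4) if perm[i] == s])
                mr = np.mean([mat[i, 1] for i in range(4) if perm[i] == r])
                scores.append(round(math.log1p(ml * mr), 12))
            expected.add(tuple(scores))
        got = {
            tuple(round(v, 12) for v in null.scores[p].reshape(-1))
            for p in range(6)
        }
        assert got == expected

    def test_exhaustive_pvalues_match_add_one_formula(self):
        mat = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 3.0], [0.0, 4.0]])
        ds = make_dataset(mat, ["A", "A", "B", "B"], ["lig", "rec"])
        kb = Knowledgebase(pairs=[LRPair("lig", "rec", "toy", "high")])
        null = shared_permutation_null(ds, kb, default_cfg(), exhaustive=True)
        run = run_ccc(ds, kb, default_cfg(min_detection_fraction=0.0), null=null)
        for _, row in run.table.iterrows():
            i = null.cell_types.index(row["sender"])
            j = null.cell_types.index(row["receiver"])
            count = int((null.scores[:, i, j, 0] >= row["score"]).sum())
            assert row["p_value"] == pytest.approx((1 + count) / (1 + 6))


class TestPerPairNull:
    def test_shuffle_counter_n2_p(self, planted_two_type_ds, one_pair_kb):
        cfg = default_cfg(n_permutations=3, permutation_scheme="per_pair")
        null = per_pair_permutation_null(planted_two_type_ds, one_pair_kb, cfg)
        assert null.n_shuffle_evaluations == 4 * 3  # N=2 types

    def test_counter_ratio_is_n_squared(self, small_ds, toy_kb):
        P = 5
        shared = shared_permutation_null(
            small_ds, toy_kb, default_cfg(n_permutations=P)
        )
        per_pair = per_pair_permutation_null(
            small_ds, toy_kb,
            default_cfg(n_permutations=P, permutation_scheme="per_pair"),
        )
        n = len(small_ds.cell_types)
        assert per_pair.n_shuffle_evaluations // shared.n_shuffle_evaluations == n * n

    def test_fixed_seed_determinism(self, planted_two_type_ds, one_pair_kb):
        cfg = default_cfg(n_permutations=10, permutation_scheme="per_pair", seed=5)
        a = per_pair_permutation_null(planted_two_type_ds, one_pair_kb, cfg)
        b = per_pair_permutation_null(planted_two_type_ds, one_pair_kb, cfg)
        np.testing.assert_array_equal(a.scores, b.scores)


class TestRunCCC:
    def test_planted_signal_direction(self, planted_two_type_ds, one_pair_kb):
        run = run_ccc(planted_two_type_ds, one_pair_kb, default_cfg())
        t = run.table.set_index(["sender", "receiver"])
        assert t.loc[("A", "B"), "significant"]
        assert t.loc[("A", "B"), "p_value"] < 0.05
        assert t.loc[("B", "A"), "score"] == 0.0
        assert t.loc[("B", "A"), "p_value"] == 1.0

    def test_missing_gene_pair_skipped(self, planted_two_type_ds):
        kb = Knowledgebase(pairs=[
            LRPair("lig", "rec", "toy", "high"),
            LRPair("ghost", "rec", "toy", "low"),
        ])
        run = run_ccc(planted_two_type_ds, kb, default_cfg())
        assert len(run.skipped_pairs) == 1
        assert run.skipped_pairs[0][0].ligand == "ghost"
        assert set(run.table["ligand"]) == {"lig"}

    def test_detection_boundary_exactly_ten_percent_retained(self):
        # 100 sender cells with the ligand in exactly 10; receiver side fine
        mat = np.zeros((200, 2))
        mat[:10, 0] = 5.0
        mat[100:, 1] = 5.0
        ds = make_dataset(mat, ["A"] * 100 + ["B"] * 100, ["lig", "rec"])
        kb = Knowledgebase(pairs=[LRPair("lig", "rec", "toy", "high")])
        t = run_ccc(ds, kb, default_cfg()).table.set_index(["sender", "receiver"])
        assert t.loc[("A", "B"), "ligand_detect_frac"] == pytest.approx(0.10)
        assert not t.loc[("A", "B"), "filtered"]

    def test_detection_nine_percent_filtered(self):
        mat = np.zeros((200, 2))
        mat[:9, 0] = 5.0
        mat[100:, 1] = 5.0
        ds = make_dataset(mat, ["A"] * 100 + ["B"] * 100, ["lig", "rec"])
        kb = Knowledgebase(pairs=[LRPair("lig", "rec", "toy", "high")])
        t = run_ccc(ds, kb, default_cfg()).table.set_index(["sender", "receiver"])
        row = t.loc[("A", "B")]
        assert row["ligand_detect_frac"] == pytest.approx(0.09)
        assert row["filtered"] and not row["significant"]
        assert "ligand" in row["filter_reason"]

    def test_less_than_two_types_rejected(self, one_pair_kb):
        ds = make_dataset(np.ones((3, 2)), ["A"] * 3, ["lig", "rec"])
        with pytest.raises(ValueError, match="2 cell types"):
            run_ccc(ds, one_pair_kb, default_cfg())

    def test_significant_iff_p_below_threshold_and_unfiltered(self, small_ds, toy_kb):
        run = run_ccc(small_ds, toy_kb, default_cfg())
        t = run.table
        expected = (t["p_value"] < run.config.p_threshold) & ~t["filtered"]
        assert (t["significant"] == expected).all()


class TestSummaries:
    def make_results(self, rows):
        import pandas as pd

        df = pd.DataFrame(
            rows,
            columns=["sender", "receiver", "pathway", "score", "significant"],
        )
        df["filtered"] = False
        return df

    def test_single_event(self):
        res = self.make_results([("A", "B", "P", 2.0, True)])
        s = summarize_celltypes(res).set_index("cell_type")
        assert s.loc["A", "outgoing_sum"] == 2.0
        assert s.loc["A", "incoming_sum"] == 0.0
        assert s.loc["B", "incoming_sum"] == 2.0
        assert s.loc["B", "outgoing_sum"] == 0.0

    def test_no_significant_events(self):
        res = self.make_results([("A", "B", "P", 2.0, False)])
        s = summarize_celltypes(res)
        assert (s[["incoming_sum", "outgoing_sum"]] == 0).all().all()

    def test_conservation_incoming_equals_outgoing(self, small_ds, toy_kb):
        run = run_ccc(small_ds, toy_kb, default_cfg())
        s = summarize_celltypes(run.table)
        assert s["incoming_sum"].sum() == pytest.approx(s["outgoing_sum"].sum())
        assert s["incoming_sum"].sum() == pytest.approx(
            run.table.loc[run.table["significant"], "score"].sum()
        )

    def test_pathway_grouping_addition(self):
        res = self.make_results([
            ("A", "B", "JAK-STAT", 1.0, True),
            ("A", "B", "JAK-STAT", 0.5, True),
            ("A", "B", "Notch", 0.7, False),
        ])
        out = summarize_pathways(res)
        assert len(out) == 1
        assert out.iloc[0]["score_sum"] == pytest.approx(1.5)

    def test_pathway_grouping_matches_brute_force(self, small_ds, toy_kb):
        run = run_ccc(small_ds, toy_kb, default_cfg())
        out = summarize_pathways(run.table).set_index(["pathway", "sender", "receiver"])
        sig = run.table[run.table["significant"]]
        expected = {}
        for _, r in sig.iterrows():
            k = (r["pathway"], r["sender"], r["receiver"])
            expected[k] = expected.get(k, 0.0) + r["score"]
        assert len(out) == len(expected)
        for k, v in expected.items():
            assert out.loc[k, "score_sum"] == pytest.approx(v)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_permutations": 0},
            {"p_threshold": 0.0},
            {"p_threshold": 1.0},
            {"min_detection_fraction": 1.0},
            {"permutation_scheme": "bogus"},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            CCCConfig(**kw)
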