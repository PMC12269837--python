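import numpy as np
import pytest

from lrcomm.afm import (
    ClassifierThresholds,
    InterfaceMetrics,
    METRIC_NAMES,
    ModelPrediction,
    aggregate_models,
    calibrate_thresholds,
    classify_ppi,
    compute_clis,
    compute_lis,
    compute_metrics,
    inverted_pae,
    load_model,
    screen_classify,
    write_pae_json,
    write_structure,
)
from lrcomm.synth import simulate_pae_pair


def make_model(pae_inter, l1=2, l2=2, coords=None, iptm=0.5):
    """Model with both inter-chain blocks set to ``pae_inter``."""
    n = l1 + l2
    pae = np.full((n, n), 30.0)
    np.fill_diagonal(pae, 0.0)
    pae_inter = np.asarray(pae_inter, dtype=float)
    pae[:l1, l1:] = pae_inter
    pae[l1:, :l1] = pae_inter.T
    if coords is None:
        coords = np.arange(n * 3, dtype=float).reshape(n, 3) * 100
    return ModelPrediction(pae=pae, chain_lengths=(l1, l2), coords=coords,
                           iptm=iptm, model_confidence=iptm)


class TestInvertedPae:
    @pytest.mark.parametrize("pae,expected", [(0, 1.0), (12, 0.0), (6, 0.5), (30, 0.0)])
    def test_linear_formula(self, pae, expected):
        assert inverted_pae(pae) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            inverted_pae(-1.0)


class TestLis:
    def test_all_zero_pae_gives_one(self):
        assert compute_lis(make_model(np.zeros((2, 2)))) == 1.0

    def test_all_beyond_cutoff_gives_zero(self):
        assert compute_lis(make_model(np.full((2, 2), 13.0))) == 0.0

    def test_hand_computed_block(self):
        # inter-chain PAE {3, 6, 9, 30}: qualifying inverted values {.75,.5,.25}
        m = make_model(np.array([[3.0, 6.0], [9.0, 30.0]]))
        assert compute_lis(m) == pytest.approx(0.5)

    def test_monotone_under_pae_increase(self):
        # increase keeps every entry inside the local area, so the mean
        # inverted PAE must drop (entries leaving the <=12 set could
        # otherwise raise the mean of the survivors)
        rng = np.random.default_rng(0)
        block = rng.uniform(0, 10, size=(3, 3))
        lo = compute_lis(make_model(block, l1=3, l2=3))
        hi = compute_lis(make_model(block + 1.5, l1=3, l2=3))
        assert hi < lo


class TestClis:
    def test_no_contacts_gives_zero(self):
        m = make_model(np.zeros((2, 2)))  # coords far apart by construction
        assert compute_clis(m) == 0.0

    def test_single_contact_pair(self):
        coords = np.array(
            [[0, 0, 0], [500, 0, 0], [0, 4, 0], [900, 0, 0]], dtype=float
        )  # only residue 0 of each chain in contact
        m = make_model(np.full((2, 2), 6.0), coords=coords)
        assert compute_clis(m) == pytest.approx(0.5)

    def test_matches_brute_force_double_loop(self):
        pred = simulate_pae_pair(12, 9, interface_size=5, interface_pae=4.0,
                                 pae_jitter=1.0, seed=3)
        m = pred.models[0]
        l1, l2 = m.chain_lengths
        vals = []
        for i in range(l1):
            for j in range(l2):
                d = np.linalg.norm(m.coords[i] - m.coords[l1 + j])
                if d <= 8.0:
                    for p in (m.pae[i, l1 + j], m.pae[l1 + j, i]):
                        if p <= 12.0:
                            vals.append((12.0 - p) / 12.0)
        expected = float(np.mean(vals)) if vals else 0.0
        assert compute_clis(m) == pytest.approx(expected)

    def test_equals_lis_when_everything_in_contact(self):
        # all four residues within 8 A of the other chain
        coords = np.array(
            [[0, 0, 0], [2, 0, 0], [0, 3, 0], [2, 3, 0]], dtype=float
        )
        m = make_model(np.array([[3.0, 6.0], [9.0, 2.0]]), coords=coords)
        assert compute_clis(m) == pytest.approx(compute_lis(m))

    def test_pae_requirement_flag(self):
        coords = np.array(
            [[0, 0, 0], [500, 0, 0], [0, 4, 0], [900, 0, 0]], dtype=float
        )
        m = make_model(np.full((2, 2), 20.0), coords=coords)
        assert compute_clis(m, require_pae=True) == 0.0
        assert compute_clis(m, require_pae=False) == 0.0  # inverted(20) clamps to 0


class TestAggregate:
    def mk(self, lis, clis=0.1, iptm=0.5):
        return InterfaceMetrics(lis=lis, clis=clis, lis_x_clis=lis * clis,
                                iptm=iptm, model_confidence=iptm)

    def test_single_model_identity(self):
        m = self.mk(0.3)
        out = aggregate_models([m])
        assert out.as_dict() == pytest.approx(m.as_dict())

    def test_two_model_mean(self):
        out = aggregate_models([self.mk(0.2), self.mk(0.4)])
        assert out.lis == pytest.approx(0.3)

    def test_five_model_hand_means_and_product_rule(self):
        lis = [0.1, 0.2, 0.3, 0.4, 0.5]
        clis = [0.5, 0.4, 0.3, 0.2, 0.1]
        models = [self.mk(l, c) for l, c in zip(lis, clis)]
        out = aggregate_models(models)
        assert out.lis == pytest.approx(np.mean(lis))
        assert out.clis == pytest.approx(np.mean(clis))
        # mean of per-model products, not product of means
        assert out.lis_x_clis == pytest.approx(
            np.mean([l * c for l, c in zip(lis, clis)])
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_models([])


class TestCalibration:
    def test_counting_oracle_1_to_100(self):
        scores = {m: np.arange(1.0, 101.0) for m in METRIC_NAMES}
        thr = calibrate_thresholds(scores, fpr=0.10)
        for m in METRIC_NAMES:
            assert thr.cutoffs[m] == 90.0
            assert (scores[m] > thr.cutoffs[m]).mean() <= 0.10

    def test_degenerate_all_equal(self):
        scores = {m: np.full(50, 0.3) for m in METRIC_NAMES}
        thr = calibrate_thresholds(scores)
        assert all(c == 0.3 for c in thr.cutoffs.values())

    def test_fpr_guarantee_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            scores = {m: rng.beta(2, 5, size=333) for m in METRIC_NAMES}
            thr = calibrate_thresholds(scores, fpr=0.10)
            for m in METRIC_NAMES:
                assert (scores[m] > thr.cutoffs[m]).mean() <= 0.10

    def test_too_few_negatives_rejected(self):
        with pytest.raises(ValueError):
            calibrate_thresholds({m: np.arange(5.0) for m in METRIC_NAMES})


class TestClassify:
    thr = ClassifierThresholds(cutoffs={m: 0.5 for m in METRIC_NAMES})

    def mk(self, n_passing):
        vals = [0.9 if i < n_passing else 0.1 for i in range(5)]
        return InterfaceMetrics(*vals)

    @pytest.mark.parametrize("n,expected", [
        (5, "positive"), (2, "positive"), (1, "negative"), (0, "negative"),
    ])
    def test_quorum_rule(self, n, expected):
        label, passes = classify_ppi(self.mk(n), self.thr)
        assert label == expected
        assert sum(passes.values()) == n

    def test_monotone_in_each_metric(self):
        base = self.mk(1)
        label_base, _ = classify_ppi(base, self.thr)
        for m in METRIC_NAMES:
            boosted = InterfaceMetrics(**{**base.as_dict(), m: 0.95})
            label_boost, passes = classify_ppi(boosted, self.thr)
            assert sum(passes.values()) >= 1
            if label_base == "positive":
                assert label_boost == "positive"

    def test_missing_metric_rejected(self):
        thr = ClassifierThresholds(cutoffs={"lis": 0.5})
        with pytest.raises(ValueError, match="missing"):
            classify_ppi(self.mk(5), thr)


class TestScreen:
    @pytest.mark.parametrize("iptm,lis,expected", [
        (0.4551, 0.0, "putative_interaction"),   # ipTM boundary inclusive
        (0.40, 0.2471, "putative_interaction"),  # LIS branch boundary
        (0.10, 0.10, "no_call"),
        (0.4550, 0.2470, "no_call"),
    ])
    def test_threshold_rule(self, iptm, lis, expected):
        assert screen_classify(iptm, lis) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            screen_classify(1.2, 0.0)


class TestIO:
    def test_round_trip_preserves_metrics(self, tmp_path):
        pred = simulate_pae_pair(8, 6, interface_size=4, interface_pae=5.0,
                                 pae_jitter=0.5, seed=5)
        m = pred.models[0]
        pj = tmp_path / "pae.json"
        st = tmp_path / "model.cif"
        write_pae_json(m, pj, ptm=0.5)
        write_structure(m, st)
        back = load_model(pj, st)
        assert back.chain_lengths == m.chain_lengths
        assert compute_lis(back) == pytest.approx(compute_lis(m))
        assert compute_clis(back) == pytest.approx(compute_clis(m))

    def test_pdb_output_too(self, tmp_path):
        pred = simulate_pae_pair(5, 5, interface_size=2)
        m = pred.models[0]
        pj, st = tmp_path / "p.json", tmp_path / "m.pdb"
        write_pae_json(m, pj)
        write_structure(m, st)
        back = load_model(pj, st)
        assert compute_clis(back) == pytest.approx(compute_clis(m))

    def test_non_square_pae_rejected(self, tmp_path):
        import json

        p = tmp_path / "bad.json"
        p.write_text(json.dumps({"predicted_aligned_error": [[1, 2, 3], [4, 5, 6]]}))
        from lrcomm.afm import load_pae_json

        with pytest.raises(ValueError, match="square"):
            load_pae_json(p)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            ModelPrediction(pae=np.zeros((3, 3)), chain_lengths=(2, 2),
                            coords=np.zeros((4, 3)), iptm=0.5,
                            model_confidence=0.5)

    def test_metrics_counts(self):
        pred = simulate_pae_pair(6, 6, interface_size=6, interface_pae=6.0)
        m = compute_metrics(pred.models[0])
        assert m.n_local_pairs == 2 * 36   # both inter-chain blocks qualify
        assert m.n_contact_pairs == 2 * 6  # interface diagonal, both blocks
        assert m.lis_x_clis == pytest.approx(m.lis * m.clis)
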