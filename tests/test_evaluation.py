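"""Ground-truth generation, confusion scoring and graph demographics."""
import numpy as np
import pytest

from hyperbundle import evaluation
from hyperbundle.bundling import HyperedgePartition
from hyperbundle.connectivity import SynchronyGraph, cplv_matrix
from hyperbundle.signals import TimeSeriesSet


class TestGroundTruth:
    def test_perfect_matching_at_full_scale(self):
        gt = evaluation.generate_ground_truth(400, seed=1)
        assert gt.n_edges == 200
        assert np.all(gt.degrees() == 1)

    def test_small_case(self):
        gt = evaluation.generate_ground_truth(4, seed=2)
        assert gt.n_edges == 2

    def test_odd_count_rejected(self):
        with pytest.raises(ValueError):
            evaluation.generate_ground_truth(5, seed=3)

    def test_different_seeds_differ(self):
        a = evaluation.generate_ground_truth(400, seed=4)
        b = evaluation.generate_ground_truth(400, seed=5)
        assert a.edges != b.edges


class TestConfusion:
    def test_perfect_recovery(self):
        gt = evaluation.generate_ground_truth(20, seed=1)
        c = evaluation.confusion(gt.edges, gt)
        assert c.tpr == 1.0 and c.fpr == 0.0

    def test_empty_observation(self):
        gt = evaluation.generate_ground_truth(20, seed=2)
        c = evaluation.confusion([], gt)
        assert c.tpr == 0.0 and c.tnr == 1.0

    def test_count_conservation(self):
        gt = evaluation.generate_ground_truth(30, seed=3)
        rng = np.random.default_rng(4)
        observed = {
            (int(i), int(j))
            for i, j in rng.integers(0, 30, size=(40, 2))
            if i != j
        }
        c = evaluation.confusion(observed, gt)
        assert c.tp + c.fp + c.tn + c.fn == 30 * 29 // 2

    def test_mask_excludes_pairs(self):
        gt = evaluation.generate_ground_truth(10, seed=5)
        mask = np.zeros((10, 10), dtype=bool)
        np.fill_diagonal(mask, True)
        some_true = sorted(gt.edges)[0]
        mask[some_true] = mask[some_true[::-1]] = True
        c = evaluation.confusion(gt.edges, gt, mask=mask)
        assert c.n_true == gt.n_edges - 1
        assert c.tp + c.fp + c.tn + c.fn == 45 - 1

    def test_out_of_range_edge_rejected(self):
        gt = evaluation.generate_ground_truth(10, seed=6)
        with pytest.raises(ValueError):
            evaluation.confusion([(0, 99)], gt)

    def test_fpr_inflation_arithmetic(self):
        out = evaluation.fpr_inflation(0.03, n_other=80000, n_true=200)
        assert out["false_positives"] == pytest.approx(2400)
        assert out["ratio_to_true"] == pytest.approx(12)
        assert evaluation.n_other_pairs(400, 200) == 79600


class TestHyperedgeScores:
    def _gt(self):
        # perfect matching on 8 parcels: true edges (0,1) (2,3) (4,5) (6,7)
        return evaluation.GroundTruthGraph(
            n_parcels=8, sources=[0, 2, 4, 6], targets=[1, 3, 5, 7]
        )

    def test_ideal_bundling(self):
        gt = self._gt()
        # each hyperedge = one true edge plus its spurious halo
        observed = [(0, 1), (0, 3), (2, 3), (4, 5), (6, 7)]
        part = HyperedgePartition(
            hyperedges=[{0, 1}, {2}, {3}, {4}], cl=0.15, theta=2, n_edges=5
        )
        s = evaluation.hyperedge_scores(part, gt, observed)
        assert s.sensitivity == 1.0
        assert s.separability == 1.0
        assert s.specificity == 1.0

    def test_single_blob_partition(self):
        gt = self._gt()
        observed = [(0, 1), (2, 3), (4, 5)]
        part = HyperedgePartition(
            hyperedges=[{0, 1, 2}], cl=0.15, theta=2, n_edges=3
        )
        s = evaluation.hyperedge_scores(part, gt, observed)
        assert s.separability == 0.0  # no single-truth hyperedge exists

    def test_all_false_hyperedges(self):
        gt = self._gt()
        observed = [(0, 2), (1, 3)]
        part = HyperedgePartition(
            hyperedges=[{0}, {1}], cl=0.15, theta=2, n_edges=2
        )
        s = evaluation.hyperedge_scores(part, gt, observed)
        assert s.sensitivity == 0.0 and s.specificity == 0.0 and s.separability == 0.0


def _graph_from_phases(phases):
    ts = TimeSeriesSet(
        data=np.exp(1j * phases), fs=100.0, f0=10.0, m=5.0, independent=True
    )
    return cplv_matrix(ts)


class TestDemographics:
    def test_true_edges_dominate_and_iplv_equals_plv_at_quarter_lag(self):
        rng = np.random.default_rng(0)
        n, ns = 8, 2000
        gt = evaluation.GroundTruthGraph(
            n_parcels=n, sources=[0, 2, 4, 6], targets=[1, 3, 5, 7]
        )
        phases = rng.uniform(-np.pi, np.pi, size=(ns, n))
        for src, tgt in zip(gt.sources, gt.targets):
            phases[:, tgt] = (
                phases[:, src] - np.pi / 2 + 0.4 * rng.standard_normal(ns)
            )
        table, hists = evaluation.graph_demographics(
            {"truth": _graph_from_phases(phases)}, gt
        )
        t = table.set_index("edge_class")
        assert t.loc["true", "mean_iplv"] > 5 * t.loc["other", "mean_iplv"]
        # quarter-cycle lag: iPLV of true edges ~ PLV of true edges
        assert t.loc["true", "mean_iplv"] == pytest.approx(
            t.loc["true", "mean_plv"], rel=0.05
        )
        # uncoupled pairs: |Im| projection is below the modulus on average
        assert t.loc["other", "mean_plv"] > t.loc["other", "mean_iplv"]
        assert t.loc["true", "n_edges"] == 4
        assert t.loc["other", "n_edges"] == n * (n - 1) // 2 - 4
        counts, _ = hists[("truth", "true")]
        assert counts.sum() == 4

    def test_mixing_inflates_plv_more_than_iplv(self, zero_lag_stats):
        # direction test over 100 seeds: real-weight mixing of uncorrelated
        # sources raises PLV strongly, iPLV stays at its null mean
        s = zero_lag_stats
        d_plv = s["mixed_plv"].mean() - s["null_plv"].mean()
        d_iplv = s["mixed_iplv"].mean() - s["null_iplv"].mean()
        assert d_plv > 5 * abs(d_iplv)
        assert d_plv > 0.05

    def test_mixing_pulls_phase_lag_toward_zero_more_when_coupling_weak(self):
        from hyperbundle import mixing, signals

        w = 0.25
        model = mixing.MixingModel(weights=np.array([[1.0, w], [w, 1.0]]))
        step = signals.decimation_step(10.0, 5.0, 100.0)
        n_raw = 999 * step + 1 + 3

        def mean_angle_shift(coupling, seeds):
            shifts = []
            for seed in seeds:
                ts = signals.morlet_noise(n_raw, 2, seed=seed)
                ts.data[:, 1] = signals.couple_pair(
                    ts.data[:, 0], coupling, 3, seed=seed + 5000
                )
                dec = signals.decimate_independent(ts, 1000, step=step)
                base = np.angle(cplv_matrix(dec).cplv[0, 1])
                mixed = np.angle(
                    cplv_matrix(mixing.apply_mixing(dec, model)).cplv[0, 1]
                )
                shifts.append(abs(np.angle(np.exp(1j * (mixed - base)))))
            return np.mean(shifts)

        seeds = range(100, 120)
        assert mean_angle_shift(0.3, seeds) > mean_angle_shift(0.9, seeds)
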