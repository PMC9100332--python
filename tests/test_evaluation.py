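"""Protocol partitioning, query sampling, and the metric suite."""

import numpy as np
import pytest

from ecgscope.evaluation import (
    MetricsReport, ProtocolConfig, ProtocolInfeasibleError,
    UndefinedMetricError, identification_accuracy, partition_recording,
    roc_metrics, run_protocol, sample_queries,
)
from ecgscope.model import ECGPairClassifier, ModelConfig
from ecgscope.preprocessing import ECGRecording, SEGMENT_SAMPLES
from ecgscope.synthetic import EASY_NOISE, synth_registry


def recording_of(seconds, rate=128.0):
    rng = np.random.default_rng(0)
    return ECGRecording(rng.normal(size=int(seconds * rate)), rate, "p1")


class TestPartition:
    def test_spans(self):
        cfg = ProtocolConfig(r=32, t=0, p=256, n=8, v=12, h=23)
        rec = recording_of(300)
        enroll, window = partition_recording(rec, cfg)
        assert enroll == (0, 32 * 128)
        assert window == (32 * 128, 288 * 128)

    def test_gap_shifts_window(self):
        cfg = ProtocolConfig(r=10, t=5, p=10, n=2, v=2, h=4)
        _, window = partition_recording(recording_of(30), cfg)
        assert window == (15 * 128, 25 * 128)

    def test_too_short_names_deficit(self):
        cfg = ProtocolConfig(r=10, t=5, p=10, n=2, v=2, h=4)
        with pytest.raises(ProtocolInfeasibleError, match="short by"):
            partition_recording(recording_of(24.9), cfg)


class TestSampleQueries:
    def test_single_possible_window(self, rng):
        samples = np.random.default_rng(1).normal(size=128 * 10)
        window = (0, 384)      # p = 3 s: only one valid start
        q = sample_queries(samples, window, 5, rng)
        assert q.shape == (5, SEGMENT_SAMPLES)
        assert np.allclose(q[0], q[1])

    def test_queries_inside_window(self):
        samples = np.random.default_rng(2).normal(size=128 * 300)
        rng = np.random.default_rng(3)
        window = (128 * 32, 128 * 288)
        q = sample_queries(samples, window, 64, rng)
        assert q.shape == (64, SEGMENT_SAMPLES)

    def test_seeded_reproducibility(self):
        samples = np.random.default_rng(2).normal(size=128 * 40)
        a = sample_queries(samples, (0, 128 * 40), 8, np.random.default_rng(9))
        b = sample_queries(samples, (0, 128 * 40), 8, np.random.default_rng(9))
        assert np.array_equal(a, b)


class TestRocMetrics:
    def test_perfect_separation(self):
        out = roc_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert out["auc"] == pytest.approx(1.0)
        assert out["eer"] == pytest.approx(0.0)

    def test_null_scores_auc_half(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(size=10_000)
        labels = rng.uniform(size=10_000) < 0.5
        out = roc_metrics(scores, labels)
        assert out["auc"] == pytest.approx(0.5, abs=0.02)
        assert out["eer"] == pytest.approx(0.5, abs=0.02)

    def test_matches_bruteforce_threshold_enumeration(self, rng):
        scores = rng.uniform(size=400)
        labels = rng.uniform(size=400) < 0.4
        out = roc_metrics(scores, labels)
        # brute force over every score as threshold
        thresholds = np.concatenate([np.unique(scores), [np.inf]])
        fprs, tprs = [1.0], [1.0]
        for th in thresholds:
            pred = scores >= th
            tprs.append((pred & labels).sum() / labels.sum())
            fprs.append((pred & ~labels).sum() / (~labels).sum())
        order = np.lexsort((tprs, fprs))
        fprs, tprs = np.array(fprs)[order], np.array(tprs)[order]
        auc_bf = np.trapezoid(tprs, fprs)
        assert out["auc"] == pytest.approx(auc_bf, abs=1e-6)
        # EER bracket: brute-force crossing of FPR and FNR
        diffs = fprs - (1 - tprs)
        k = int(np.searchsorted(diffs, 0))
        lo = min(fprs[k - 1], 1 - tprs[k]) - 1e-9
        hi = max(fprs[k], 1 - tprs[k - 1]) + 1e-9
        assert lo <= out["eer"] <= hi

    def test_spec_example_scores(self):
        out = roc_metrics([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 1])
        # exhaustive enumeration: best split puts 2 genuine above, the
        # third genuine (0.2) below the single impostor (0.4)
        assert out["auc"] == pytest.approx(2 / 3, abs=1e-9)
        assert 0.0 < out["eer"] <= 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_metrics([0.1, 0.9], [1, 1])

    def test_tpr_at_fpr_monotone(self, rng):
        scores = rng.normal(size=500) + np.where(rng.uniform(size=500) < 0.5, 1.0, 0.0)
        labels = scores > np.median(scores)
        scores = scores + rng.normal(0, 0.5, 500)
        out = roc_metrics(scores, labels, fpr_levels=(0.01, 0.05, 0.10))
        t = out["tpr_at_fpr"]
        assert t["0.01"] <= t["0.05"] <= t["0.1"]


class TestIdentificationAccuracy:
    def test_extremes_and_hand_count(self):
        assert identification_accuracy([1, 2, 3], [1, 2, 3]) == 1.0
        assert identification_accuracy([1, 2, 3], [4, 5, 6]) == 0.0
        decisions = [0, 1, 2, 2, 1, 0, 3, 3, 1, 0]
        truths = [0, 1, 1, 2, 1, 3, 3, 0, 1, 0]
        # hand tally: positions 0,1,3,4,6,8,9 match -> 7 of 10
        assert identification_accuracy(decisions, truths) == pytest.approx(0.7)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            identification_accuracy([1], [1, 2])


@pytest.fixture(scope="module")
def protocol_setup():
    registry = synth_registry(1, [12], [128.0], 55, duration_s=48.0,
                              noise=EASY_NOISE)
    model = ECGPairClassifier(ModelConfig.scaled(1 / 32, seed=0))
    model.eval()
    return model, registry


class TestRunProtocol:
    def test_report_structure_and_roc_consistency(self, protocol_setup):
        model, registry = protocol_setup
        cfg = ProtocolConfig(r=6, t=0, p=30, n=4, v=2, h=8)
        rng = np.random.default_rng(1)
        report, = run_protocol(model, registry, [cfg], rng)
        assert isinstance(report, MetricsReport)
        assert report.n_queries == 32
        iv = report.individual_verification
        assert 0 <= iv["eer"] <= 1 and 0 <= iv["auc"] <= 1
        t = iv["tpr_at_fpr"]
        assert t["0.01"] <= t["0.05"] <= t["0.1"]
        sv = report.scope_verification
        assert sv is not None
        assert sv["tpr_at_fpr"]["0.1"] <= sv["tpr_at_fpr"]["0.3"]
        d = report.to_dict()
        assert d["config"]["h"] == 8

    def test_reproducible_under_seed(self, protocol_setup):
        model, registry = protocol_setup
        cfg = ProtocolConfig(r=6, t=0, p=20, n=2, v=2, h=6)
        a, = run_protocol(model, registry, [cfg], np.random.default_rng(7))
        b, = run_protocol(model, registry, [cfg], np.random.default_rng(7))
        assert a.identification_accuracy == b.identification_accuracy
        assert a.individual_verification["eer"] == b.individual_verification["eer"]

    def test_infeasible_protocol_raises(self, protocol_setup):
        model, registry = protocol_setup
        cfg = ProtocolConfig(r=32, t=60, p=32, n=2, v=2, h=4)   # 124 s > 48 s
        with pytest.raises(ProtocolInfeasibleError):
            run_protocol(model, registry, [cfg], np.random.default_rng(0))

    def test_genuine_trials_per_identity(self, protocol_setup):
        model, registry = protocol_setup
        cfg = ProtocolConfig(r=6, t=0, p=20, n=3, v=1, h=5)
        report, = run_protocol(model, registry, [cfg], np.random.default_rng(2),
                               scope_verification=False)
        assert report.scope_verification is None
        assert report.n_queries == 15          # n genuine trials per identity


class TestSessionModes:
    def make_registry(self):
        from ecgscope.dataset import DatabaseEntry, DatabaseRegistry
        from ecgscope.synthetic import NoiseSpec, sample_identity, synth_recording
        morph = sample_identity(3)
        recs = [synth_recording(morph, NoiseSpec(0.01, 0.0), 10.0, 128.0,
                                session_start=ss, rng_seed=i,
                                identity_id="p1", database_id="db")
                for i, ss in enumerate([0.0, 100.0, 200.0])]
        return DatabaseRegistry([DatabaseEntry("db", 128.0, {"p1": recs})])

    def test_enrollment_from_earliest_session(self):
        from ecgscope.evaluation import _select_spans
        registry = self.make_registry()
        cfg = ProtocolConfig(r=6, t=0, p=4, n=1, v=1, h=1)
        for mode, which in (("session-short", 1), ("session-long", 2)):
            enroll_rec, samples, window = _select_spans(registry, "p1", cfg, mode)
            assert enroll_rec.session_start == 0.0
            expected = registry.recordings_of("p1")[which]
            assert np.array_equal(samples, expected.samples)
            assert window == (0, 4 * 128)
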