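"""Evaluation protocol: enrollment / time separation / classification
window, query sampling, voting, and the biometric metric suite.

A long continuous recording is carved into an enrollment span of r
seconds, a gap of t seconds (the time separation), and a classification
window of p seconds from which n query segments are sampled.  Every
query is classified against the full scope of h enrolled identities
with v votes.  Metrics: individual verification reports TPR at 1/5/10%
FPR, EER and ROC-AUC over genuine claims (the true position's score)
versus impostor claims (every other position's score); scope
verification reports TPR at 10/20/30% FPR, EER and ROC-AUC over
in-scope versus out-of-scope queries; closed identification reports
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

from .dataset import DatabaseRegistry
from .model import ECGPairClassifier
from .preprocessing import (SEGMENT_SAMPLES, TARGET_RATE_HZ, ECGRecording,
                            FilterSpec, resample, segment_windows)
from .voting import Vote, VoteSet, scope_verify, split_enrollment, vote

__all__ = [
    "ProtocolConfig", "MetricsReport", "partition_recording",
    "sample_queries", "roc_metrics", "identification_accuracy",
    "run_protocol", "ProtocolInfeasibleError", "UndefinedMetricError",
]

_INDIVIDUAL_FPR_LEVELS = (0.01, 0.05, 0.10)
_SCOPE_FPR_LEVELS = (0.10, 0.20, 0.30)


class ProtocolInfeasibleError(ValueError):
    """Recording too short for the requested (r, t, p) partition."""


class UndefinedMetricError(ValueError):
    """ROC requested with only one class present."""


@dataclass(frozen=True)
class ProtocolConfig:
    """(r, t, p, n, v, h): enrollment seconds, time-separation seconds,
    classification-window seconds, queries per window, votes, scope size."""

    r: float = 32.0
    t: float = 0.0
    p: float = 32.0
    n: int = 8
    v: int = 12
    h: int = 8

    def __post_init__(self):
        if self.r < 3 or self.p < 3:
            raise ValueError("r and p must be at least 3 s")
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if self.n < 1 or self.v < 1 or self.h < 1:
            raise ValueError("n, v, h must be >= 1")


@dataclass
class MetricsReport:
    config: ProtocolConfig
    identification_accuracy: float
    individual_verification: dict
    scope_verification: dict | None
    n_queries: int

    def to_dict(self) -> dict:
        out = {
            "config": {k: getattr(self.config, k) for k in "rtpnvh"},
            "identification_accuracy": self.identification_accuracy,
            "individual_verification": self.individual_verification,
            "scope_verification": self.scope_verification,
            "n_queries": self.n_queries,
        }
        return out


def partition_recording(recording: ECGRecording, cfg: ProtocolConfig
                        ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Enrollment span [0, r) and classification window [r+t, r+t+p), as
    half-open sample intervals at 128 Hz."""
    rate = TARGET_RATE_HZ
    duration = recording.samples.size / recording.sampling_rate
    needed = cfg.r + cfg.t + cfg.p
    if duration < needed:
        raise ProtocolInfeasibleError(
            f"recording lasts {duration:.2f} s but the protocol needs "
            f"r+t+p = {needed:.2f} s (short by {needed - duration:.2f} s)")
    enroll = (0, int(round(cfg.r * rate)))
    start = int(round((cfg.r + cfg.t) * rate))
    window = (start, start + int(round(cfg.p * rate)))
    return enroll, window


def sample_queries(samples_128hz: np.ndarray, window: tuple[int, int],
                   n: int, rng: np.random.Generator,
                   spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """n preprocessed query segments with uniform random starts inside the
    window; returns (n, 384)."""
    lo, hi = window
    max_start = hi - SEGMENT_SAMPLES
    if max_start < lo:
        raise ProtocolInfeasibleError("classification window shorter than 3 s")
    offsets = rng.integers(lo, max_start + 1, size=n)
    return segment_windows(samples_128hz, offsets, spec)


def roc_metrics(scores, labels, fpr_levels=_INDIVIDUAL_FPR_LEVELS) -> dict:
    """ROC by threshold sweep: EER (linear interpolation at FPR = FNR),
    trapezoidal AUC, and TPR read off at the requested FPR levels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise UndefinedMetricError("both genuine and impostor scores required")
    fpr, tpr, _ = _skm.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    fnr = 1.0 - tpr
    diff = fpr - fnr                      # non-decreasing along the sweep
    i = int(np.searchsorted(diff, 0.0))
    if i == 0:
        eer = float(fpr[0])
    elif i >= diff.size:
        eer = float(fnr[-1])
    else:
        # linear interpolation between the bracketing ROC points
        d0, d1 = diff[i - 1], diff[i]
        w = 0.0 if d1 == d0 else -d0 / (d1 - d0)
        eer = float((1 - w) * fpr[i - 1] + w * fpr[i])
    tpr_at = {level: float(np.interp(level, fpr, tpr)) for level in fpr_levels}
    return {
        "eer": eer,
        "auc": auc,
        "tpr_at_fpr": {f"{level:g}": t for level, t in tpr_at.items()},
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist()},
    }


def identification_accuracy(decisions, truths) -> float:
    """Fraction of final identifications matching the true position."""
    decisions = np.asarray(decisions)
    truths = np.asarray(truths)
    if decisions.size != truths.size or decisions.size == 0:
        raise ValueError("decisions and truths must have equal positive length")
    return float((decisions == truths).mean())


def _session_key(rec: ECGRecording) -> float:
    return rec.session_start


def _select_spans(registry: DatabaseRegistry, ident: str, cfg: ProtocolConfig,
                  session_mode: str):
    """Choose (enrollment samples, window samples, window span) for one
    identity.

    continuous: one long recording carved per Fig-style partition.
    session-short: enrollment from the earliest session, window from the
    second-earliest.  session-long: window from the latest session.
    """
    recs = sorted(registry.recordings_of(ident), key=_session_key)
    if session_mode == "continuous" or len(recs) == 1:
        rec = recs[0]
        _, window = partition_recording(rec, cfg)
        samples = resample(rec).samples
        return rec, samples, window
    enroll_rec = recs[0]
    window_rec = recs[1] if session_mode == "session-short" else recs[-1]
    samples = resample(window_rec).samples
    stop = min(int(round(cfg.p * TARGET_RATE_HZ)), samples.size)
    if stop < SEGMENT_SAMPLES:
        raise ProtocolInfeasibleError(
            f"{ident}: classification session shorter than 3 s")
    return enroll_rec, samples, (0, stop)


def run_protocol(model: ECGPairClassifier, registry: DatabaseRegistry,
                 configs: list[ProtocolConfig],
                 rng: np.random.Generator,
                 spec: FilterSpec = FilterSpec(),
                 scope_verification: bool = True,
                 session_mode: str = "continuous") -> list[MetricsReport]:
    """Enroll h identities, run n queries each, and aggregate the metric
    suite; one report per configuration.

    The first h registry identities form the scope (ordinal position =
    class label); remaining identities supply out-of-scope queries for
    scope verification, with the negative count matched to the positive
    count.
    """
    reports = []
    for cfg in configs:
        idents = registry.all_identities
        if len(idents) < cfg.h:
            raise ValueError(f"registry has {len(idents)} identities; "
                             f"scope needs {cfg.h}")
        scope_ids = idents[:cfg.h]
        holdout_ids = idents[cfg.h:]

        enroll = np.empty((cfg.h, cfg.v, SEGMENT_SAMPLES))
        queries = np.empty((cfg.h, cfg.n, SEGMENT_SAMPLES))
        for i, ident in enumerate(scope_ids):
            enroll_rec, samples, window = _select_spans(
                registry, ident, cfg, session_mode)
            enroll[i] = split_enrollment(enroll_rec, cfg.r, cfg.v, spec)
            queries[i] = sample_queries(samples, window, cfg.n, rng, spec)

        ver_scores, dists = _voted_outputs(
            model, enroll, queries.reshape(-1, SEGMENT_SAMPLES))
        truths = np.repeat(np.arange(cfg.h), cfg.n)
        decisions = []
        for k in range(truths.size):
            votes = VoteSet([Vote(dists[j, k], ver_scores[j, k])
                             for j in range(cfg.v)])
            decisions.append(vote(votes))
        identified = np.array([d.final_identified for d in decisions])
        id_acc = identification_accuracy(identified, truths)

        mean_ver = np.stack([d.verification_scores for d in decisions])
        genuine = mean_ver[np.arange(truths.size), truths]
        mask = np.ones_like(mean_ver, dtype=bool)
        mask[np.arange(truths.size), truths] = False
        impostor = mean_ver[mask]
        individual = roc_metrics(
            np.concatenate([genuine, impostor]),
            np.concatenate([np.ones_like(genuine, bool),
                            np.zeros_like(impostor, bool)]),
            _INDIVIDUAL_FPR_LEVELS)

        scope_report = None
        if scope_verification and holdout_ids:
            pos = np.array([scope_verify(d)[0] for d in decisions])
            neg = _out_of_scope_scores(model, registry, holdout_ids, enroll,
                                       cfg, rng, spec, session_mode,
                                       count=pos.size)
            scope_report = roc_metrics(
                np.concatenate([pos, neg]),
                np.concatenate([np.ones_like(pos, bool),
                                np.zeros_like(neg, bool)]),
                _SCOPE_FPR_LEVELS)

        reports.append(MetricsReport(
            config=cfg, identification_accuracy=id_acc,
            individual_verification=individual,
            scope_verification=scope_report,
            n_queries=int(truths.size)))
    return reports


def _voted_outputs(model: ECGPairClassifier, enroll: np.ndarray,
                   queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run every query against every vote's scope.

    enroll: (h, v, 384); queries: (B, 384).  Returns verification
    probabilities and identification distributions of shape (v, B, h).
    Vote j pairs the j-th enrollment window of every scope identity with
    the query.
    """
    h, v, _ = enroll.shape
    b = queries.shape[0]
    vers = np.empty((v, b, h))
    dists = np.empty((v, b, h))
    for j in range(v):
        scope = np.broadcast_to(enroll[:, j, :], (b, h, SEGMENT_SAMPLES))
        out = model.predict(scope, queries)
        vers[j] = out.verification_probs
        dists[j] = out.id_distribution
    return vers, dists


def _out_of_scope_scores(model, registry, holdout_ids, enroll, cfg, rng,
                         spec, session_mode, count) -> np.ndarray:
    """Scope-verification scores for queries from identities outside the
    scope, `count` in total, spread over the holdout identities."""
    per = int(np.ceil(count / len(holdout_ids)))
    neg_queries = []
    for ident in holdout_ids:
        _, samples, window = _select_spans(registry, ident, cfg, session_mode)
        neg_queries.append(sample_queries(samples, window, per, rng, spec))
    neg = np.concatenate(neg_queries)[:count]
    vers, dists = _voted_outputs(model, enroll, neg)
    scores = []
    for k in range(neg.shape[0]):
        votes = VoteSet([Vote(dists[j, k], vers[j, k]) for j in range(cfg.v)])
        scores.append(scope_verify(vote(votes))[0])
    return np.asarray(scores)
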