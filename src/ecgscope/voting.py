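"""Voting over multiple enrollment windows, and scope verification.

An enrollment recording longer than 3 s is split into v evenly spaced
(possibly overlapping) 3-second windows.  Each window pairs with the
query for one classification, giving v votes.  The most-voted identity
wins the final identification; per-position individual verification is
the majority of thresholded per-vote decisions.  Ties are broken by the
largest mean probability.  Scope verification then reads the final
individual verification at the winning position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import (SEGMENT_SAMPLES, TARGET_RATE_HZ, ECGRecording,
                            FilterSpec, finalize_windows, resample)

__all__ = [
    "Vote", "VoteSet", "FinalDecision",
    "enrollment_offsets", "split_enrollment", "vote", "scope_verify",
]


@dataclass(frozen=True)
class Vote:
    """One classification result over a fixed scope."""

    id_distribution: np.ndarray      # (h,), sums to 1
    verification_probs: np.ndarray   # (h,) in (0, 1)

    @property
    def identified(self) -> int:
        return int(np.argmax(self.id_distribution))


@dataclass
class VoteSet:
    votes: list[Vote]

    def __post_init__(self):
        if not self.votes:
            raise ValueError("vote set must contain at least one vote")
        h = self.votes[0].id_distribution.shape[0]
        if any(v.id_distribution.shape != (h,) for v in self.votes):
            raise ValueError("all votes must cover the same scope")

    @property
    def v(self) -> int:
        return len(self.votes)

    @property
    def h(self) -> int:
        return self.votes[0].id_distribution.shape[0]


@dataclass
class FinalDecision:
    final_identified: int                 # scope position (0-based)
    verification_decisions: np.ndarray    # (h,) bool, majority at 0.5
    verification_scores: np.ndarray       # (h,) mean verification probability
    mean_id_distribution: np.ndarray      # (h,)


def enrollment_offsets(r: float, v: int) -> np.ndarray:
    """Start offsets (samples at 128 Hz) of v windows evenly spaced over
    an r-second enrollment: [0, (r-3)*128] inclusive; windows overlap
    whenever (r-3)/(v-1) < 3."""
    if v < 1:
        raise ValueError(f"v must be >= 1, got {v}")
    if r < SEGMENT_SAMPLES / TARGET_RATE_HZ:
        raise ValueError(f"enrollment must cover at least 3 s, got {r} s")
    span = (r - SEGMENT_SAMPLES / TARGET_RATE_HZ) * TARGET_RATE_HZ
    if v == 1:
        return np.zeros(1, dtype=np.intp)
    return np.round(np.arange(v) * span / (v - 1)).astype(np.intp)


def split_enrollment(recording: ECGRecording, r: float, v: int,
                     spec: FilterSpec = FilterSpec(),
                     start_sample: int = 0) -> np.ndarray:
    """v preprocessed 384-sample windows from the first r seconds of the
    recording (resampled to 128 Hz); returns an array of shape (v, 384)."""
    rec = resample(recording)
    offsets = enrollment_offsets(r, v) + start_sample
    if offsets[-1] + SEGMENT_SAMPLES > rec.samples.size:
        raise ValueError(
            f"recording covers {rec.duration_s:.1f} s; enrollment needs "
            f"{start_sample / TARGET_RATE_HZ + r:.1f} s")
    windows = rec.samples[offsets[:, None] + np.arange(SEGMENT_SAMPLES)[None, :]]
    return finalize_windows(windows, spec)


def _majority_tiebreak(counts: np.ndarray, means: np.ndarray) -> int:
    """Most-voted index; equal votes resolved by largest mean probability."""
    top = counts.max()
    tied = np.flatnonzero(counts == top)
    if tied.size == 1:
        return int(tied[0])
    return int(tied[np.argmax(means[tied])])


def vote(votes: VoteSet, threshold: float = 0.5) -> FinalDecision:
    """Aggregate v votes into a final decision.

    Identification: modal argmax position, ties broken by the largest
    mean identification probability.  Individual verification per
    position: majority of per-vote thresholded decisions, an exact split
    resolved by whether the mean probability clears the threshold.
    """
    dists = np.stack([v.id_distribution for v in votes.votes])   # (v, h)
    vers = np.stack([v.verification_probs for v in votes.votes])  # (v, h)
    h = votes.h
    counts = np.bincount(dists.argmax(axis=1), minlength=h)
    mean_dist = dists.mean(axis=0)
    winner = _majority_tiebreak(counts, mean_dist)
    accept_votes = (vers >= threshold).sum(axis=0)
    mean_ver = vers.mean(axis=0)
    decisions = np.where(accept_votes * 2 == votes.v,
                         mean_ver >= threshold,
                         accept_votes * 2 > votes.v)
    return FinalDecision(final_identified=winner,
                         verification_decisions=decisions,
                         verification_scores=mean_ver,
                         mean_id_distribution=mean_dist)


def scope_verify(decision: FinalDecision,
                 threshold: float = 0.5) -> tuple[float, bool]:
    """Scope verification reads the final individual verification at the
    winning position: returns its mean-probability score and the accept
    decision at `threshold` (the continuous score feeds ROC sweeps)."""
    score = float(decision.verification_scores[decision.final_identified])
    return score, bool(score >= threshold)
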