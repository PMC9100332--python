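"""Synthetic multi-identity ECG corpora for desk-scale experiments.

Each identity is a stable waveform morphology: five Gaussian bumps per
beat standing in for the P, Q, R, S and T waves, with per-identity
amplitudes, widths, latencies, and a mean RR interval with Gaussian
jitter (heart-rate variability).  Recordings add white measurement noise
and sinusoidal baseline wander, and can drift their morphology linearly
with elapsed wall-clock time to emulate the slow waveform change that
separates an enrollment session from a query taken days later.

This is not a physiological simulator: it is a controllable stand-in
with the statistical features the identification pipeline depends on —
per-identity morphology stability, inter-identity separability, noise,
multiple sampling rates, and time-dependent drift.

Two documented noise regimes are provided: `EASY_NOISE` (near-clean,
used for learnability checks where nearest-template classification is
perfect) and `REALISTIC_NOISE` (visible noise and wander).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import DatabaseEntry, DatabaseRegistry
from .preprocessing import ECGRecording, SEGMENT_SECONDS

__all__ = [
    "IdentityMorphology", "NoiseSpec", "EASY_NOISE", "REALISTIC_NOISE",
    "sample_identity", "synth_recording", "synth_registry",
]

#: Priors for identity morphology, wide enough that independent draws are
#: separable, narrow enough to stay ECG-shaped.  Amplitudes are in
#: arbitrary mV-like units; widths/latencies in seconds relative to the
#: R-like bump at the beat center.
_AMP_RANGES = [(0.05, 0.30), (-0.30, -0.05), (0.8, 1.8), (-0.50, -0.10), (0.10, 0.65)]
_WIDTH_RANGES = [(0.018, 0.050), (0.006, 0.018), (0.010, 0.028),
                 (0.006, 0.018), (0.045, 0.110)]
_LAT_RANGES = [(-0.28, -0.15), (-0.050, -0.022), (-0.004, 0.004),
               (0.022, 0.050), (0.18, 0.35)]
#: Mean RR interval prior: uniform on [0.50, 1.20] s (50-120 bpm); its
#: mean, 0.85 s, is the documented prior mean checked by tests.
_MEAN_RR_RANGE = (0.50, 1.20)
MEAN_RR_PRIOR_MEAN = sum(_MEAN_RR_RANGE) / 2.0
_RR_JITTER_RANGE = (0.010, 0.040)

#: fractional morphology change per hour is capped at this total change
_DRIFT_CAP = 0.4

#: registries reject identity draws closer than this normalized parameter
#: distance to an already-drawn identity (continuous priors would otherwise
#: produce occasional near-duplicate morphologies)
MIN_IDENTITY_SEPARATION = 1.0


def _morph_vector(m: "IdentityMorphology") -> np.ndarray:
    """Morphology parameters normalized by their prior ranges."""
    span = np.array([hi - lo for lo, hi in
                     (*_AMP_RANGES, *_WIDTH_RANGES, *_LAT_RANGES,
                      _MEAN_RR_RANGE)])
    raw = np.concatenate([m.bump_amplitudes, m.bump_widths,
                          m.bump_latencies, [m.mean_rr]])
    return raw / span


@dataclass
class IdentityMorphology:
    """Per-identity waveform parameters (P, Q, R, S, T order)."""

    bump_amplitudes: np.ndarray
    bump_widths: np.ndarray
    bump_latencies: np.ndarray
    mean_rr: float
    rr_jitter_sd: float
    drift_rate: float = 0.0
    #: fixed signed directions (5 amplitudes + RR) along which drift acts
    drift_directions: np.ndarray = field(
        default_factory=lambda: np.ones(6))

    def __post_init__(self):
        self.bump_amplitudes = np.asarray(self.bump_amplitudes, dtype=float)
        self.bump_widths = np.asarray(self.bump_widths, dtype=float)
        self.bump_latencies = np.asarray(self.bump_latencies, dtype=float)
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if np.any(self.bump_widths <= 0):
            raise ValueError("bump widths must be positive")
        if np.abs(self.bump_amplitudes).argmax() != 2:
            raise ValueError("the R-like bump (index 2) must dominate in magnitude")

    def at_time(self, hours: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        """Morphology after `hours` of linear drift (capped fractional change).

        Amplitudes drift fully, widths at half rate, latencies shift by up
        to 40 ms, and the RR interval drifts at quarter rate — slow
        waveform change dominates over rhythm change.
        """
        frac = min(abs(self.drift_rate) * max(hours, 0.0), _DRIFT_CAP)
        s = self.drift_directions
        amps = self.bump_amplitudes * (1.0 + s[:5] * frac)
        widths = self.bump_widths * (1.0 + s[:5] * 0.5 * frac)
        lats = self.bump_latencies + s[:5] * frac * 0.1 * np.array(
            [1.0, 0.3, 0.0, 0.3, 1.0])
        rr = self.mean_rr * (1.0 + s[5] * 0.25 * frac)
        return amps, widths, lats, rr


@dataclass(frozen=True)
class NoiseSpec:
    """Additive corruption: white noise plus sinusoidal baseline wander."""

    white_sd: float = 0.05
    baseline_wander_amp: float = 0.15
    baseline_wander_hz: float = 0.25

    def __post_init__(self):
        if min(self.white_sd, self.baseline_wander_amp, self.baseline_wander_hz) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.baseline_wander_hz >= 0.5:
            raise ValueError("baseline wander must stay below 0.5 Hz")


EASY_NOISE = NoiseSpec(white_sd=0.01, baseline_wander_amp=0.03)
REALISTIC_NOISE = NoiseSpec(white_sd=0.06, baseline_wander_amp=0.20)


def sample_identity(rng_seed: int, drift_rate: float = 0.0) -> IdentityMorphology:
    """Draw a morphology from the documented priors; deterministic per seed."""
    rng = np.random.default_rng(rng_seed)
    amps = np.array([rng.uniform(lo, hi) for lo, hi in _AMP_RANGES])
    widths = np.array([rng.uniform(lo, hi) for lo, hi in _WIDTH_RANGES])
    lats = np.array([rng.uniform(lo, hi) for lo, hi in _LAT_RANGES])
    mean_rr = rng.uniform(*_MEAN_RR_RANGE)
    jitter = rng.uniform(*_RR_JITTER_RANGE)
    directions = rng.choice([-1.0, 1.0], size=6)
    return IdentityMorphology(amps, widths, lats, mean_rr, jitter,
                              drift_rate=drift_rate,
                              drift_directions=directions)


def synth_recording(morph: IdentityMorphology, noise: NoiseSpec,
                    duration_s: float, rate_hz: float,
                    session_start: float = 0.0, rng_seed: int = 0,
                    identity_id: str = "synthetic",
                    database_id: str = "synthdb") -> ECGRecording:
    """Render a beat train with jittered RR intervals, drift, and noise.

    Drift is evaluated at absolute time (session_start plus position in
    the recording), so a later session or a late portion of a very long
    recording both show drifted morphology.
    """
    if duration_s < SEGMENT_SECONDS:
        raise ValueError(
            f"duration_s must be at least {SEGMENT_SECONDS} s, got {duration_s}")
    if rate_hz < 64:
        raise ValueError(f"rate_hz must be at least 64 Hz, got {rate_hz}")
    rng = np.random.default_rng(rng_seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    sig = np.zeros(n)

    # beat centers: accumulate jittered RR intervals (RR itself may drift)
    beat_time = 0.0
    first = True
    while beat_time < duration_s + 0.5:
        hours = (session_start + beat_time) / 3600.0
        amps, widths, lats, rr = morph.at_time(hours)
        if not first:
            step = rr + (rng.normal(0.0, morph.rr_jitter_sd)
                         if morph.rr_jitter_sd > 0 else 0.0)
            beat_time += max(step, 0.2)
        first = False
        for a, w, lat in zip(amps, widths, lats):
            center = beat_time + lat
            lo = max(int((center - 5 * w) * rate_hz), 0)
            hi = min(int((center + 5 * w) * rate_hz) + 1, n)
            if hi <= lo:
                continue
            tt = t[lo:hi]
            sig[lo:hi] += a * np.exp(-0.5 * ((tt - center) / w) ** 2)

    if noise.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        sig += noise.baseline_wander_amp * np.sin(
            2 * np.pi * noise.baseline_wander_hz * t + phase)
    if noise.white_sd > 0:
        sig += rng.normal(0.0, noise.white_sd, size=n)
    return ECGRecording(samples=sig, sampling_rate=rate_hz,
                        identity_id=identity_id, database_id=database_id,
                        session_start=session_start)


def synth_registry(n_databases: int, identities_per_db: list[int],
                   rates: list[float], rng_seed: int,
                   duration_s: float = 64.0,
                   noise: NoiseSpec = EASY_NOISE,
                   drift_rate: float = 0.0,
                   split_ratios: list[tuple[int, int]] | None = None,
                   session_start: float = 0.0,
                   min_separation: float = MIN_IDENTITY_SEPARATION
                   ) -> DatabaseRegistry:
    """Build a multi-database registry of synthetic identities.

    Each database gets its own sampling rate and identity count; every
    identity receives one long recording.  Identity draws closer than
    `min_separation` (normalized parameter distance) to an existing
    identity are rejected and redrawn, so registries never contain
    near-duplicate morphologies.  All randomness fans out from
    `rng_seed` through per-identity child seeds, so regeneration with
    the same seed is byte-identical.
    """
    if not (len(identities_per_db) == n_databases == len(rates)):
        raise ValueError("identities_per_db and rates must have n_databases entries")
    if split_ratios is not None and len(split_ratios) != n_databases:
        raise ValueError("split_ratios must have n_databases entries")
    root = np.random.SeedSequence(rng_seed)
    db_seeds = root.spawn(n_databases)
    databases = []
    drawn: list[np.ndarray] = []
    for d, (count, rate, db_ss) in enumerate(zip(identities_per_db, rates, db_seeds)):
        db_id = f"synthdb{d}"
        recordings: dict[str, list[ECGRecording]] = {}
        for i, ident_ss in enumerate(db_ss.spawn(count)):
            ident_id = f"{db_id}_id{i:03d}"
            seeds = iter(ident_ss.generate_state(64) >> 1)      # < 2**31
            rec_seed = int(next(seeds))
            for morph_seed in seeds:
                morph = sample_identity(int(morph_seed), drift_rate=drift_rate)
                v = _morph_vector(morph)
                if not drawn or min(np.linalg.norm(v - u) for u in drawn) \
                        >= min_separation:
                    break
            else:
                raise RuntimeError("could not draw a sufficiently distinct "
                                   "identity; lower min_separation")
            drawn.append(v)
            rec = synth_recording(morph, noise, duration_s, rate,
                                  session_start=session_start,
                                  rng_seed=rec_seed,
                                  identity_id=ident_id, database_id=db_id)
            recordings[ident_id] = [rec]
        ratio = (split_ratios[d] if split_ratios is not None
                 else (max(count - count // 3, 1), count // 3))
        databases.append(DatabaseEntry(database_id=db_id, sampling_rate=rate,
                                       recordings=recordings, split_ratio=ratio))
    return DatabaseRegistry(databases=databases)
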