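"""Training/validation example generation over a multi-database registry.

One classification example is a scope of h enrolled segments J, a query
segment Gq, and the scope position of the query's true identity.  The
single-example generator draws the scope from one uniformly chosen
database, fills it up from other databases when that database is too
small, picks the query identity uniformly within the scope, and — for
the true identity only — cuts two non-overlapping windows from the same
recording, so the enrolled/query pair shares an identity but never
shares samples.  All h+1 windows are band-pass filtered and then
standardized.

Scope size is 32 during training-dataset generation; the trained model
itself accepts any h.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocessing import (SEGMENT_SAMPLES, ECGRecording, FilterSpec,
                            finalize_windows, resample)

__all__ = [
    "DatabaseEntry", "DatabaseRegistry", "Scope", "ClassificationExample",
    "SegmentRef", "Dataset", "InsufficientRegistryError",
    "single_example", "build_dataset", "split_registry",
    "TRAIN_SCOPE_SIZE",
]

#: scope size used when generating training/validation datasets
TRAIN_SCOPE_SIZE = 32

#: attempts to find two disjoint windows before re-drawing the identity
_MAX_OFFSET_TRIES = 64
_MAX_IDENTITY_TRIES = 16


class InsufficientRegistryError(ValueError):
    """Registry cannot supply a full scope of unique identities."""


@dataclass
class DatabaseEntry:
    """One database: a sampling rate, identities with recordings, and a
    train:validation split ratio (counts of identities)."""

    database_id: str
    sampling_rate: float
    recordings: dict[str, list[ECGRecording]]
    split_ratio: tuple[int, int] = (0, 0)

    @property
    def identities(self) -> list[str]:
        return list(self.recordings.keys())


@dataclass
class DatabaseRegistry:
    databases: list[DatabaseEntry]

    def __post_init__(self):
        seen: set[str] = set()
        for db in self.databases:
            for ident in db.identities:
                if ident in seen:
                    raise ValueError(f"identity_id {ident!r} appears in two databases")
                seen.add(ident)
        self._cache_128: dict[tuple[str, int], np.ndarray] = {}

    @property
    def all_identities(self) -> list[str]:
        return [i for db in self.databases for i in db.identities]

    @property
    def n_identities(self) -> int:
        return sum(len(db.recordings) for db in self.databases)

    def database_of(self, identity_id: str) -> DatabaseEntry:
        for db in self.databases:
            if identity_id in db.recordings:
                return db
        raise KeyError(identity_id)

    def recordings_of(self, identity_id: str) -> list[ECGRecording]:
        return self.database_of(identity_id).recordings[identity_id]

    def samples_128(self, identity_id: str, recording_index: int) -> np.ndarray:
        """128 Hz samples of one recording, resampled once and cached."""
        key = (identity_id, recording_index)
        if key not in self._cache_128:
            rec = self.recordings_of(identity_id)[recording_index]
            self._cache_128[key] = resample(rec).samples
        return self._cache_128[key]

    def content_hash(self) -> str:
        """Hash of identities and signal content, for dataset provenance."""
        digest = hashlib.sha256()
        for db in self.databases:
            digest.update(db.database_id.encode())
            digest.update(np.float64(db.sampling_rate).tobytes())
            for ident, recs in db.recordings.items():
                digest.update(ident.encode())
                for rec in recs:
                    digest.update(np.ascontiguousarray(rec.samples[:256]).tobytes())
        return digest.hexdigest()[:16]


@dataclass(frozen=True)
class SegmentRef:
    """Provenance of one window: where in the registry it was cut."""

    database_id: str
    identity_id: str
    recording_index: int
    offset: int


@dataclass
class Scope:
    """Ordered enrolled identities; position (0-based) is the class label."""

    members: list[str]

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError("scope members must be unique")
        if len(self.members) < 2:
            raise ValueError("scope needs at least 2 identities")

    @property
    def h(self) -> int:
        return len(self.members)


@dataclass
class ClassificationExample:
    """Scope segments J (h, 384), query segment Gq (384,), true label."""

    scope_segments: np.ndarray
    query_segment: np.ndarray
    label: int                      # 0-based scope position of the true identity
    scope: Scope
    scope_refs: list[SegmentRef] = field(default_factory=list)
    query_ref: SegmentRef | None = None

    def __post_init__(self):
        self.scope_segments = np.asarray(self.scope_segments)
        self.query_segment = np.asarray(self.query_segment)
        h = len(self.scope.members)
        if self.scope_segments.shape != (h, SEGMENT_SAMPLES):
            raise ValueError("scope_segments must be (h, 384)")
        if self.query_segment.shape != (SEGMENT_SAMPLES,):
            raise ValueError("query_segment must be (384,)")
        if not 0 <= self.label < h:
            raise ValueError("label out of scope")

    @property
    def true_ordinal(self) -> int:
        """1-based scope position of the true identity."""
        return self.label + 1


def _random_offset(rng: np.random.Generator, n_samples: int) -> int:
    hi = n_samples - SEGMENT_SAMPLES
    if hi < 0:
        raise IndexError("recording shorter than one segment")
    return int(rng.integers(0, hi + 1))


def _disjoint_offsets(rng: np.random.Generator, n_samples: int) -> tuple[int, int]:
    """Two window starts with |difference| >= 384 (sample-disjoint windows)."""
    if n_samples < 2 * SEGMENT_SAMPLES:
        raise IndexError("recording too short for two disjoint windows")
    for _ in range(_MAX_OFFSET_TRIES):
        a = _random_offset(rng, n_samples)
        b = _random_offset(rng, n_samples)
        if abs(a - b) >= SEGMENT_SAMPLES:
            return a, b
    raise IndexError("could not find disjoint windows")


def single_example(registry: DatabaseRegistry, rng: np.random.Generator,
                   scope_size: int = TRAIN_SCOPE_SIZE,
                   spec: FilterSpec = FilterSpec()) -> ClassificationExample:
    """Generate one classification example.

    Steps: draw the scope from one uniformly chosen database (filling up
    one identity at a time from uniformly chosen databases, skipping
    duplicates, when it is smaller than the scope); pick the query
    identity uniformly; cut two disjoint windows from one of its
    recordings; cut one window per other scope member; filter then
    standardize everything.
    """
    if registry.n_identities < scope_size:
        raise InsufficientRegistryError(
            f"registry has {registry.n_identities} identities; "
            f"scope needs {scope_size}")
    databases = [db for db in registry.databases if db.recordings]
    first_db = databases[rng.integers(len(databases))]
    idents = first_db.identities
    take = min(scope_size, len(idents))
    members = [idents[i] for i in rng.choice(len(idents), size=take, replace=False)]
    chosen = set(members)
    while len(members) < scope_size:
        db = databases[rng.integers(len(databases))]
        k = db.identities[rng.integers(len(db.identities))]
        if k not in chosen:
            members.append(k)
            chosen.add(k)
    scope = Scope(members)

    q_pos = int(rng.integers(scope_size))
    windows = np.empty((scope_size + 1, SEGMENT_SAMPLES))
    refs: list[SegmentRef] = []
    query_ref: SegmentRef | None = None
    for pos, ident in enumerate(members):
        db = registry.database_of(ident)
        if pos == q_pos:
            for attempt in range(_MAX_IDENTITY_TRIES):
                ridx = int(rng.integers(len(registry.recordings_of(ident))))
                samples = registry.samples_128(ident, ridx)
                try:
                    off_k, off_q = _disjoint_offsets(rng, samples.size)
                    break
                except IndexError:
                    if attempt == _MAX_IDENTITY_TRIES - 1:
                        raise
            windows[pos] = samples[off_k:off_k + SEGMENT_SAMPLES]
            windows[-1] = samples[off_q:off_q + SEGMENT_SAMPLES]
            refs.append(SegmentRef(db.database_id, ident, ridx, off_k))
            query_ref = SegmentRef(db.database_id, ident, ridx, off_q)
        else:
            ridx = int(rng.integers(len(registry.recordings_of(ident))))
            samples = registry.samples_128(ident, ridx)
            off = _random_offset(rng, samples.size)
            windows[pos] = samples[off:off + SEGMENT_SAMPLES]
            refs.append(SegmentRef(db.database_id, ident, ridx, off))

    finalized = finalize_windows(windows, spec)
    return ClassificationExample(
        scope_segments=finalized[:-1], query_segment=finalized[-1],
        label=q_pos, scope=scope, scope_refs=refs, query_ref=query_ref)


@dataclass
class Dataset:
    """Materialized examples: scope tensors, queries, labels, provenance."""

    scope: np.ndarray       # (N, h, 384) float32
    query: np.ndarray       # (N, 384) float32
    labels: np.ndarray      # (N,) int16, 0-based
    provenance: list[dict] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.scope.shape[0]

    @property
    def h(self) -> int:
        return self.scope.shape[1]

    def save(self, directory, chunk_size: int = 4096) -> Path:
        """Chunked .npz storage plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        n = len(self)
        chunks = []
        for c, start in enumerate(range(0, max(n, 1), chunk_size)):
            stop = min(start + chunk_size, n)
            name = f"chunk_{c:04d}.npz"
            np.savez(directory / name, scope=self.scope[start:stop],
                     query=self.query[start:stop], labels=self.labels[start:stop])
            chunks.append({"file": name, "count": stop - start})
            if n == 0:
                break
        manifest = {"count": n, "h": int(self.scope.shape[1]) if n else 0,
                    "chunks": chunks, "meta": self.meta}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        (directory / "provenance.json").write_text(json.dumps(self.provenance))
        return directory

    @classmethod
    def load(cls, directory) -> "Dataset":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        scopes, queries, labels = [], [], []
        for chunk in manifest["chunks"]:
            with np.load(directory / chunk["file"]) as arc:
                scopes.append(arc["scope"])
                queries.append(arc["query"])
                labels.append(arc["labels"])
        prov_path = directory / "provenance.json"
        provenance = json.loads(prov_path.read_text()) if prov_path.exists() else []
        if manifest["count"] == 0:
            return cls(np.empty((0, 0, SEGMENT_SAMPLES), np.float32),
                       np.empty((0, SEGMENT_SAMPLES), np.float32),
                       np.empty((0,), np.int16), provenance, manifest.get("meta", {}))
        return cls(np.concatenate(scopes), np.concatenate(queries),
                   np.concatenate(labels), provenance, manifest.get("meta", {}))


def build_dataset(registry: DatabaseRegistry, count: int,
                  rng: np.random.Generator,
                  scope_size: int = TRAIN_SCOPE_SIZE,
                  spec: FilterSpec = FilterSpec(),
                  keep_provenance: bool = True) -> Dataset:
    """Run the single-example generator `count` times over `registry`.

    The registry passed in should already be the desired partition
    (training or validation); partitions are produced by split_registry.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    scope = np.empty((count, scope_size, SEGMENT_SAMPLES), dtype=np.float32)
    query = np.empty((count, SEGMENT_SAMPLES), dtype=np.float32)
    labels = np.empty(count, dtype=np.int16)
    provenance: list[dict] = []
    for i in range(count):
        ex = single_example(registry, rng, scope_size, spec)
        scope[i] = ex.scope_segments
        query[i] = ex.query_segment
        labels[i] = ex.label
        if keep_provenance:
            provenance.append({
                "scope": [[r.database_id, r.identity_id, r.recording_index, r.offset]
                          for r in ex.scope_refs],
                "query": [ex.query_ref.database_id, ex.query_ref.identity_id,
                          ex.query_ref.recording_index, ex.query_ref.offset],
                "label": int(ex.label),
            })
    meta = {"scope_size": scope_size, "registry_hash": registry.content_hash()}
    if count == 0:
        scope = np.empty((0, 0, SEGMENT_SAMPLES), dtype=np.float32)
    return Dataset(scope, query, labels, provenance, meta)


def split_registry(registry: DatabaseRegistry,
                   ratios: dict[str, tuple[int, int]] | None = None,
                   rng: np.random.Generator | None = None
                   ) -> tuple[DatabaseRegistry, DatabaseRegistry]:
    """Partition every database's identities into disjoint train/validation
    groups with the requested counts.

    `ratios` maps database_id to (train_count, val_count); databases not
    listed use their own split_ratio.  Order is the stored identity order
    unless an rng is given, in which case identities are shuffled first.
    """
    train_dbs, val_dbs = [], []
    for db in registry.databases:
        train_n, val_n = (ratios or {}).get(db.database_id, db.split_ratio)
        idents = db.identities
        if train_n + val_n > len(idents):
            raise ValueError(
                f"{db.database_id}: split {train_n}:{val_n} exceeds "
                f"{len(idents)} identities")
        if rng is not None:
            idents = [idents[i] for i in rng.permutation(len(idents))]
        train_ids = idents[:train_n]
        val_ids = idents[train_n:train_n + val_n]
        train_dbs.append(DatabaseEntry(
            db.database_id, db.sampling_rate,
            {i: db.recordings[i] for i in train_ids}, (train_n, 0)))
        val_dbs.append(DatabaseEntry(
            db.database_id, db.sampling_rate,
            {i: db.recordings[i] for i in val_ids}, (0, val_n)))
    return DatabaseRegistry(train_dbs), DatabaseRegistry(val_dbs)
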