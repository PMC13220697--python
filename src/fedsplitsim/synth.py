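"""Synthetic wearable-ECG heartbeat segments and federated partitioning.

The generator emits fixed-length (187-sample) heartbeat segments centred on
the R-peak, in two classes: a stereotyped normal P-QRS-T morphology and an
arrhythmic variant with a widened, attenuated and slightly delayed QRS
complex and no distinct P wave (the morphology of a typical ventricular
ectopic beat).  Both classes are a sum of Gaussian bumps plus white Gaussian
noise; the bump parameters were fixed once so that the two noiseless
templates are clearly distinct while the default noise level makes them
overlap (the per-segment optimal error is a few percent, see docs/methods.md).

Partitioning mirrors a federated study design: a whole-user global test
hold-out, the remaining users' segments distributed across ``n_clients``
silos with Dirichlet label-proportion skew (the standard non-IID label-skew
construction), and an internal 80/20 train/validation split per silo.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from ._seeding import STREAM_PARTITION, STREAM_WAVEFORM, child_rng
from .errors import ConfigurationError, DegenerateDataError

SEGMENT_LENGTH = 187
R_PEAK_INDEX = 93

# (centre, width, amplitude) of the Gaussian bumps making up each template.
_NORMAL_BUMPS = (
    (63.0, 6.0, 0.18),    # P wave
    (88.0, 1.8, -0.25),   # Q
    (93.0, 2.2, 1.00),    # R (peak defines segment centre)
    (98.0, 1.8, -0.30),   # S
    (128.0, 10.0, 0.35),  # T wave
)
_ARRHYTHMIA_BUMPS = (
    # no P wave; wide, low-amplitude, delayed QRS; broad T
    (91.0, 3.5, -0.20),
    (97.0, 5.0, 0.55),
    (104.0, 3.5, -0.25),
    (140.0, 14.0, 0.28),
)


# ---------------------------------------------------------------------------
# configs and containers


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthesis parameters for one dataset draw."""

    n_users: int = 50
    segments_per_user: int = 100
    arrhythmia_prevalence: float = 0.15
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 1 or self.segments_per_user < 1:
            raise ConfigurationError("n_users and segments_per_user must be >= 1")
        if not 0.0 <= self.arrhythmia_prevalence <= 1.0:
            raise ConfigurationError("arrhythmia_prevalence must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)


@dataclass(frozen=True)
class PartitionConfig:
    """Federated train/test partitioning parameters."""

    n_clients: int = 50
    test_fraction: float = 0.2
    dirichlet_alpha: float = 0.5
    local_val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clients < 1:
            raise ConfigurationError("n_clients must be >= 1")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigurationError("test_fraction must lie in (0, 1)")
        if self.dirichlet_alpha <= 0:
            raise ConfigurationError("dirichlet_alpha must be positive")
        if not 0.0 <= self.local_val_fraction < 1.0:
            raise ConfigurationError("local_val_fraction must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PartitionConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)


@dataclass
class SegmentSet:
    """A batch of labelled heartbeat segments.

    ``X`` is (n, 187) float64; ``y`` is (n,) int64 with 0 = normal,
    1 = arrhythmia; ``source_index`` tracks each segment's position in the
    generation order so partitions can be written as index manifests.
    """

    X: np.ndarray
    y: np.ndarray
    source_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2 or self.X.shape[1] != SEGMENT_LENGTH:
            raise ConfigurationError(
                f"segments must be (n, {SEGMENT_LENGTH}); got {self.X.shape}"
            )
        if self.y.shape != (self.X.shape[0],):
            raise ConfigurationError("labels must be one per segment")
        if not np.all(np.isfinite(self.X)):
            raise ConfigurationError("segments must be finite")
        if self.source_index is None:
            self.source_index = np.arange(len(self.y), dtype=np.int64)
        else:
            self.source_index = np.asarray(self.source_index, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.y.shape[0])

    def take(self, idx: np.ndarray) -> "SegmentSet":
        return SegmentSet(self.X[idx], self.y[idx], self.source_index[idx])

    @staticmethod
    def concat(parts: Iterable["SegmentSet"]) -> "SegmentSet":
        parts = list(parts)
        return SegmentSet(
            np.concatenate([p.X for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.source_index for p in parts]),
        )


@dataclass
class ClientSilo:
    """One simulated wearable's local data, split train/validation."""

    client_id: int
    train: SegmentSet
    validation: SegmentSet

    @property
    def n_segments(self) -> int:
        return len(self.train) + len(self.validation)


# ---------------------------------------------------------------------------
# waveform synthesis


def class_template(class_label: int) -> np.ndarray:
    """The noiseless 187-sample morphology of one class."""
    if class_label not in (0, 1):
        raise ValueError(f"class label must be 0 or 1, got {class_label!r}")
    bumps = _NORMAL_BUMPS if class_label == 0 else _ARRHYTHMIA_BUMPS
    t = np.arange(SEGMENT_LENGTH, dtype=np.float64)
    out = np.zeros(SEGMENT_LENGTH)
    for centre, width, amp in bumps:
        out += amp * np.exp(-0.5 * ((t - centre) / width) ** 2)
    return out


def generate_segment(
    class_label: int, rng: np.random.Generator, config: GeneratorConfig
) -> np.ndarray:
    """One 187-sample segment: class template plus white Gaussian noise."""
    template = class_template(class_label)
    if config.noise_sd == 0:
        return template
    return template + rng.normal(0.0, config.noise_sd, size=SEGMENT_LENGTH)


def generate_dataset(config: GeneratorConfig) -> dict[int, SegmentSet]:
    """Draw the full multi-user dataset: ``{user_id: SegmentSet}``.

    Labels are i.i.d. Bernoulli(arrhythmia_prevalence); each user has an
    independent noise stream derived from the master seed, so the dataset is
    a pure function of the config.
    """
    users: dict[int, SegmentSet] = {}
    offset = 0
    for uid in range(config.n_users):
        rng = child_rng(config.seed, STREAM_WAVEFORM, uid)
        y = (rng.random(config.segments_per_user) < config.arrhythmia_prevalence).astype(
            np.int64
        )
        X = np.stack([generate_segment(int(label), rng, config) for label in y])
        users[uid] = SegmentSet(
            X, y, np.arange(offset, offset + config.segments_per_user)
        )
        offset += config.segments_per_user
    return users


def dataset_size(dataset: dict[int, SegmentSet]) -> int:
    return sum(len(s) for s in dataset.values())


# ---------------------------------------------------------------------------
# partitioning


def _largest_remainder_counts(p: np.ndarray, n: int) -> np.ndarray:
    """Integer allocation of n items proportional to p, conserving exactly."""
    raw = p * n
    counts = np.floor(raw).astype(np.int64)
    short = n - int(counts.sum())
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def split_and_partition(
    dataset: dict[int, SegmentSet], pc: PartitionConfig
) -> tuple[SegmentSet, list[ClientSilo]]:
    """Whole-user global-test hold-out plus Dirichlet-skewed client silos.

    ``floor(test_fraction * n_users)`` users (chosen uniformly) form the
    global test set; every segment of the remaining users is assigned to
    exactly one of ``n_clients`` silos.  Per class, silo shares are drawn
    from Dirichlet(alpha,...,alpha): small alpha concentrates each class on
    few silos (strong label skew), large alpha approaches IID.
    """
    if not dataset:
        raise ConfigurationError("dataset is empty")
    rng = child_rng(pc.seed, STREAM_PARTITION)
    user_ids = np.array(sorted(dataset.keys()))
    n_test_users = int(np.floor(pc.test_fraction * len(user_ids)))
    if n_test_users < 1:
        raise ConfigurationError("test_fraction holds out zero users")
    if pc.n_clients > len(user_ids) - n_test_users:
        raise ConfigurationError(
            f"n_clients={pc.n_clients} exceeds the {len(user_ids) - n_test_users} "
            "users available after the test hold-out"
        )
    perm = rng.permutation(len(user_ids))
    test_users = user_ids[perm[:n_test_users]]
    train_users = user_ids[perm[n_test_users:]]

    global_test = SegmentSet.concat([dataset[u] for u in sorted(test_users)])
    pool = SegmentSet.concat([dataset[u] for u in sorted(train_users)])

    silo_members: list[list[int]] = [[] for _ in range(pc.n_clients)]
    for label in (0, 1):
        cls_idx = np.flatnonzero(pool.y == label)
        if len(cls_idx) == 0:
            continue
        cls_idx = rng.permutation(cls_idx)
        shares = rng.dirichlet(np.full(pc.n_clients, pc.dirichlet_alpha))
        counts = _largest_remainder_counts(shares, len(cls_idx))
        stops = np.cumsum(counts)
        start = 0
        for k, stop in enumerate(stops):
            silo_members[k].extend(cls_idx[start:stop].tolist())
            start = int(stop)

    silos = []
    for k, members in enumerate(silo_members):
        local = pool.take(np.array(sorted(members), dtype=np.int64))
        train, val = _local_split(local, pc.local_val_fraction, rng)
        silos.append(ClientSilo(client_id=k, train=train, validation=val))
    return global_test, silos


def _local_split(
    local: SegmentSet, val_fraction: float, rng: np.random.Generator
) -> tuple[SegmentSet, SegmentSet]:
    """80/20-style split, stratified by label when both labels are present."""
    n = len(local)
    if n == 0 or val_fraction == 0.0:
        return local, local.take(np.array([], dtype=np.int64))
    val_idx: list[int] = []
    labels = np.unique(local.y)
    for label in labels:
        cls = np.flatnonzero(local.y == label)
        n_val = int(np.floor(val_fraction * len(cls)))
        picked = rng.permutation(cls)[:n_val]
        val_idx.extend(picked.tolist())
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    return local.take(np.flatnonzero(~val_mask)), local.take(np.flatnonzero(val_mask))


def partition_manifest(
    global_test: SegmentSet, silos: list[ClientSilo]
) -> dict:
    """JSON-serialisable manifest: client_id -> source indices, plus test."""
    return {
        "global_test": global_test.source_index.tolist(),
        "clients": {
            str(s.client_id): {
                "train": s.train.source_index.tolist(),
                "validation": s.validation.source_index.tolist(),
            }
            for s in silos
        },
    }


def write_manifest(path: str | Path, global_test: SegmentSet, silos: list[ClientSilo]) -> None:
    with open(path, "w") as fh:
        json.dump(partition_manifest(global_test, silos), fh)


# ---------------------------------------------------------------------------
# z-score feature scaling


@dataclass(frozen=True)
class ScalerState:
    """Per-sample-position standardisation statistics (population sd)."""

    mean: np.ndarray
    sd: np.ndarray


def zscore_fit(train: SegmentSet) -> ScalerState:
    """Fit per-position mean/sd on a training set.

    Each of the 187 sample positions is treated as one feature.  Raises
    :class:`DegenerateDataError` on zero-variance positions rather than
    silently dividing by zero.
    """
    if len(train) < 2:
        raise DegenerateDataError("z-score fit needs at least 2 segments")
    mean = train.X.mean(axis=0)
    sd = train.X.std(axis=0)  # population (divide-by-n) convention
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise DegenerateDataError(
            f"zero standard deviation at sample position(s) {bad[:5].tolist()}"
        )
    return ScalerState(mean=mean, sd=sd)


def zscore_apply(state: ScalerState, segments: SegmentSet) -> SegmentSet:
    return SegmentSet(
        (segments.X - state.mean) / state.sd, segments.y, segments.source_index
    )


# ---------------------------------------------------------------------------
# CSV interchange


def write_segments_csv(path: str | Path, segments: SegmentSet, header: bool = True) -> None:
    """One row per segment: 187 sample columns then the integer label."""
    data = np.column_stack([segments.X, segments.y.astype(np.float64)])
    cols = [f"s{i}" for i in range(SEGMENT_LENGTH)] + ["label"]
    np.savetxt(
        path,
        data,
        delimiter=",",
        fmt=["%.17g"] * SEGMENT_LENGTH + ["%d"],
        header=",".join(cols) if header else "",
        comments="",
    )


def read_segments_csv(path: str | Path) -> SegmentSet:
    with open(path) as fh:
        first = fh.readline()
    skip = 1 if first.startswith("s0,") else 0
    data = np.loadtxt(path, delimiter=",", skiprows=skip, ndmin=2)
    if data.shape[1] != SEGMENT_LENGTH + 1:
        raise ConfigurationError(
            f"expected {SEGMENT_LENGTH + 1} columns, got {data.shape[1]}"
        )
    return SegmentSet(data[:, :SEGMENT_LENGTH], data[:, SEGMENT_LENGTH].astype(np.int64))
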