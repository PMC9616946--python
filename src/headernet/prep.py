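"""Dataset preparation: normalization, pink-noise balancing, partitioning.

Classification is meant to rest on waveform *shape*, not amplitude, so each
trace is z-normalized per event and per axis (mean 0, s.d. 1).  The heavy
VH/NH class imbalance is corrected by augmentation: randomly chosen header
traces are duplicated with added pink (1/f) noise scaled to sigma = 10% of
each axis' raw standard deviation, until the classes are balanced.  The
noise is added to the raw trace, before z-normalization, so the augmented
copy is a plausible raw recording in g.  Augmented events carry a flag and
are never allowed into the test partition.

Pink noise is produced by spectral shaping: a white Gaussian sequence is
transformed to the frequency domain, its amplitudes multiplied by
``f**-0.5`` (giving a 1/f power spectrum), the DC bin zeroed, and the
inverse transform normalized to unit sample variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import NH, VH, LabeledEvent, SensorEventRecord


class DegenerateTraceError(ValueError):
    """A trace axis has (near-)zero variance and cannot be z-normalized."""


@dataclass
class SplitSpec:
    """Train/validation/test fractions, stratified by label.

    The default 49/21/30 split reproduces the reference partitioning: per
    label, the test share is floored (so 904 headers give 271 test headers
    and 19,145 non-headers give 5743), validation is floored next, and the
    remainder goes to training.
    """

    train: float = 0.49
    val: float = 0.21
    test: float = 0.30
    stratify: bool = True

    def __post_init__(self) -> None:
        fracs = (self.train, self.val, self.test)
        if any(f < 0 for f in fracs) or self.train <= 0:
            raise ValueError("split fractions must be nonnegative, train positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(fracs)}")


@dataclass
class AugmentationSpec:
    """Pink-noise augmentation: noise scale relative to per-axis raw s.d."""

    sigma: float = 0.10
    target_ratio: float = 1.0  # VH:NH ratio after balancing

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")


def znormalize(trace: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Per-axis standardization to mean 0, s.d. 1 (population s.d.)."""
    trace = np.asarray(trace, dtype=float)
    sd = trace.std(axis=-1, keepdims=True)
    if np.any(sd < eps):
        raise DegenerateTraceError("constant axis cannot be z-normalized")
    return (trace - trace.mean(axis=-1, keepdims=True)) / sd


def make_pink_noise(n: int = 100, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Unit-variance pink (1/f) noise of length ``n`` via spectral shaping."""
    if n < 8:
        raise ValueError("pink noise needs n >= 8")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    white = rng.normal(size=n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5  # amplitude ~ f^-1/2 => power ~ 1/f
    shaped = np.fft.irfft(spectrum * scale, n=n)
    sd = shaped.std()
    if sd == 0:  # pragma: no cover - measure-zero draw
        return make_pink_noise(n, rng)
    return shaped / sd


def _augmented_copy(source: LabeledEvent, spec: AugmentationSpec,
                    rng: np.random.Generator, tag: int) -> LabeledEvent:
    raw = source.event.trace
    noisy = raw + np.stack([
        make_pink_noise(raw.shape[1], rng) * (spec.sigma * raw[axis].std())
        for axis in range(raw.shape[0])
    ])
    event = SensorEventRecord(
        event_id=f"{source.event.event_id}-aug{tag:04d}",
        player_id=source.event.player_id,
        session_id=source.event.session_id,
        timestamp_s=source.event.timestamp_s,
        trace=noisy,
    )
    return LabeledEvent(event=event, label=source.label,
                        matched_video_id=source.matched_video_id,
                        match_offset_s=source.match_offset_s,
                        augmented=True)


def augment_balance(dataset: Sequence[LabeledEvent], spec: AugmentationSpec,
                    rng: np.random.Generator | int | None = None) -> list[LabeledEvent]:
    """Balance classes by appending pink-noise copies of random VH traces.

    Copies are made from uniformly sampled headers with independent per-axis
    pink noise scaled by ``sigma`` times the raw copy's per-axis s.d.; the
    originals pass through unchanged and copies are flagged ``augmented``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    vh = [le for le in dataset if le.label == VH]
    nh = [le for le in dataset if le.label == NH]
    if not vh:
        raise ValueError("cannot balance a dataset with zero VHs")
    deficit = int(round(len(nh) * spec.target_ratio)) - len(vh)
    if deficit <= 0:
        return list(dataset)
    out = list(dataset)
    sources = rng.integers(0, len(vh), size=deficit)
    for tag, src in enumerate(sources):
        out.append(_augmented_copy(vh[int(src)], spec, rng, tag))
    return out


def split_counts(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    """Partition sizes (train, val, test) for ``n`` events of one label.

    The test share is floored, validation is floored next, the remainder
    trains; with the default 49/21/30 fractions, 904 headers yield a test
    partition of 271 and 19,145 non-headers one of 5743.
    """
    return _split_counts(n, spec)


def _split_counts(n: int, spec: SplitSpec) -> tuple[int, int, int]:
    n_test = int(np.floor(spec.test * n))
    n_val = int(np.floor(spec.val * n))
    n_train = n - n_test - n_val
    if n_train <= 0 or (spec.val > 0 and n_val == 0 and n >= 2):
        raise ValueError(f"dataset of {n} events too small for split fractions")
    return n_train, n_val, n_test


def split(dataset: Sequence[LabeledEvent], spec: SplitSpec,
          rng: np.random.Generator | int | None = None):
    """Random stratified partition into (train, val, test).

    Per label, the test count is the floored test fraction, validation is
    floored next, and the remainder trains.  Augmented events are kept out
    of the test partition: the test draw is made among originals only.
    """
    if not dataset:
        raise ValueError("cannot split an empty dataset")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    groups: dict[str, list[LabeledEvent]] = {}
    if spec.stratify:
        for le in dataset:
            groups.setdefault(le.label, []).append(le)
    else:
        groups["all"] = list(dataset)
    train, val, test = [], [], []
    for label in sorted(groups):
        members = groups[label]
        n_train, n_val, n_test = _split_counts(len(members), spec)
        originals = [i for i, le in enumerate(members) if not le.augmented]
        if len(originals) < n_test:
            raise ValueError(f"label {label}: not enough original events "
                             f"for an un-augmented test partition")
        test_idx = set(rng.choice(originals, size=n_test, replace=False).tolist())
        rest = [i for i in range(len(members)) if i not in test_idx]
        perm = rng.permutation(len(rest))
        val_idx = {rest[i] for i in perm[:n_val]}
        test.extend(members[i] for i in sorted(test_idx))
        val.extend(members[i] for i in sorted(val_idx))
        train.extend(members[i] for i in range(len(members))
                     if i not in test_idx and i not in val_idx)
    return train, val, test


def traces_and_labels(dataset: Sequence[LabeledEvent],
                      normalized: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Stack a labeled dataset into (X, y): X (n, 3, 100), y 1 for VH."""
    X = np.stack([le.event.trace for le in dataset])
    if normalized:
        X = np.stack([znormalize(x) for x in X])
    y = np.array([1 if le.label == VH else 0 for le in dataset], dtype=int)
    return X, y
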