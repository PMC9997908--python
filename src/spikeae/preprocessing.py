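"""Waveform preprocessing: peak alignment, unit-interval scaling, shuffling,
and Fourier-domain descriptors.

Alignment shifts every spike so its reference peak (maximum by default) sits
at a common sample index, following

    new_start = old_start - (index_align - peak)

Aligning to the middle of the window is the default since it retains both the
pre- and post-peak course of the action potential. Scaling is a single global
min-max affine map of the whole set into [0, 1] (per-spike scaling would
destroy the amplitude differences that separate units).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import blackman

from .datasets import ContinuousRecording, LabeledSpikeSet

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentSpec",
    "FourierSpec",
    "align_spikes",
    "scale_unit_interval",
    "UnitScaler",
    "shuffle_spikes",
    "fourier_features",
    "FOURIER_PARTS",
]

FOURIER_PARTS = ("real", "imaginary", "magnitude", "phase", "power", "concatenation")


@dataclass
class AlignmentSpec:
    """Where and how to align the reference peak.

    ``index_align=None`` means the middle of the window, floor(n_samples/2).
    ``mode='shift-extracted'`` shifts within the fixed window (edge samples
    replicated); ``mode='recut-from-signal'`` re-cuts the window from the
    continuous signal, which needs the recording and per-spike window origins.
    """

    index_align: int | None = None
    reference: str = "maximum-peak"
    mode: str = "shift-extracted"

    def resolve_index(self, n_samples: int) -> int:
        idx = n_samples // 2 if self.index_align is None else self.index_align
        if not 0 <= idx < n_samples:
            raise ValueError("index_align must lie in [0, n_samples)")
        return idx


@dataclass
class FourierSpec:
    part: str = "real"
    window: str = "none"

    def __post_init__(self) -> None:
        if self.part not in FOURIER_PARTS:
            raise ValueError(f"unknown Fourier descriptor {self.part!r}")
        if self.window not in ("none", "blackman"):
            raise ValueError(f"unknown window {self.window!r}")


def _reference_peaks(W: np.ndarray, reference: str) -> np.ndarray:
    if reference == "maximum-peak":
        return np.argmax(W, axis=1)
    if reference == "minimum-peak":
        return np.argmin(W, axis=1)
    raise ValueError(f"unknown reference {reference!r}")


def align_spikes(
    spikes: LabeledSpikeSet,
    spec: AlignmentSpec | None = None,
    signal: ContinuousRecording | None = None,
) -> LabeledSpikeSet:
    """Align every spike's reference peak to a common sample index."""
    spec = spec or AlignmentSpec()
    m = spikes.n_samples
    idx = spec.resolve_index(m)
    peaks = _reference_peaks(spikes.waveforms, spec.reference)

    if spec.mode == "recut-from-signal":
        if signal is None or spikes.origin_indices is None:
            raise ValueError(
                "recut-from-signal alignment needs the recording and window origins"
            )
        sig = signal.signal
        waves, labels, origins, kept = [], [], [], []
        skipped = 0
        for i in range(spikes.n_spikes):
            # Eq: new_start = old_start - (index_align - peak)
            new_start = int(spikes.origin_indices[i]) - (idx - int(peaks[i]))
            if new_start < 0 or new_start + m > len(sig):
                skipped += 1
                continue
            waves.append(sig[new_start : new_start + m])
            origins.append(new_start)
            kept.append(i)
        if skipped:
            logger.info("align_spikes: skipped %d spikes at signal edges", skipped)
        W = np.asarray(waves) if waves else np.empty((0, m))
        kept = np.asarray(kept, dtype=int)
        return LabeledSpikeSet(
            waveforms=W,
            sampling_rate=spikes.sampling_rate,
            labels=spikes.labels[kept] if spikes.labels is not None else None,
            peak_indices=_reference_peaks(W, spec.reference) if len(W) else None,
            origin_indices=np.asarray(origins, dtype=int),
            source=spikes.source,
        )

    if spec.mode != "shift-extracted":
        raise ValueError(f"unknown alignment mode {spec.mode!r}")

    W = spikes.waveforms
    out = np.empty_like(W)
    for i in range(len(W)):
        shift = idx - int(peaks[i])  # positive -> move right
        if shift == 0:
            out[i] = W[i]
        elif shift > 0:
            out[i, shift:] = W[i, :-shift]
            out[i, :shift] = W[i, 0]  # replicate leading edge
        else:
            out[i, :shift] = W[i, -shift:]
            out[i, shift:] = W[i, -1]  # replicate trailing edge
    return spikes.with_waveforms(
        out, peak_indices=_reference_peaks(out, spec.reference)
    )


class UnitScaler:
    """Global min-max map of a whole spike set into [0, 1].

    Fit once on the (post-alignment) training set and reuse for any later
    transform of the same dataset so all waveforms share one affine map.
    """

    def __init__(self) -> None:
        self.min_: float | None = None
        self.max_: float | None = None

    def fit(self, spikes: LabeledSpikeSet) -> "UnitScaler":
        lo = float(np.min(spikes.waveforms))
        hi = float(np.max(spikes.waveforms))
        if hi == lo:
            raise ValueError("constant dataset: unit-interval scale undefined")
        self.min_, self.max_ = lo, hi
        return self

    def transform(self, spikes: LabeledSpikeSet) -> LabeledSpikeSet:
        if self.min_ is None:
            raise RuntimeError("scaler not fitted")
        W = (spikes.waveforms - self.min_) / (self.max_ - self.min_)
        return spikes.with_waveforms(W)


def scale_unit_interval(spikes: LabeledSpikeSet) -> LabeledSpikeSet:
    """Min-max scale the whole set into [0, 1] with a single affine map."""
    return UnitScaler().fit(spikes).transform(spikes)


def shuffle_spikes(spikes: LabeledSpikeSet, seed: int) -> LabeledSpikeSet:
    """Permute spikes (and labels) by one seeded permutation.

    Benchmark simulation files store spikes ordered by unit, so without
    shuffling early mini-batches would be single-class.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(spikes.n_spikes)
    return spikes.with_waveforms(
        spikes.waveforms[perm],
        labels=spikes.labels[perm] if spikes.labels is not None else None,
        peak_indices=(
            spikes.peak_indices[perm] if spikes.peak_indices is not None else None
        ),
        origin_indices=(
            spikes.origin_indices[perm] if spikes.origin_indices is not None else None
        ),
    )


def fourier_features(spikes: LabeledSpikeSet, spec: FourierSpec | None = None):
    """Per-spike FFT descriptors over the non-redundant half-spectrum.

    ``part='concatenation'`` stacks real and imaginary halves, which keeps the
    transform invertible. An optional Blackman window is applied before the
    transform to emphasise the centre-aligned peak. Phase of an exactly zero
    coefficient is defined as 0.
    """
    from .models import FeatureSet  # local import to avoid a cycle

    spec = spec or FourierSpec()
    W = spikes.waveforms
    if W.shape[1] < 2:
        raise ValueError("waveform length must be >= 2")
    if spec.window == "blackman":
        W = W * blackman(W.shape[1])
    F = np.fft.rfft(W, axis=1)

    if spec.part == "real":
        X = F.real
    elif spec.part == "imaginary":
        X = F.imag
    elif spec.part == "magnitude":
        X = np.abs(F)
    elif spec.part == "power":
        X = np.abs(F) ** 2
    elif spec.part == "phase":
        X = np.where(F == 0, 0.0, np.angle(F))
    else:  # concatenation
        X = np.concatenate([F.real, F.imag], axis=1)
    return FeatureSet(
        features=np.asarray(X, dtype=float),
        method_tag=f"fourier:{spec.part}:{spec.window}",
    )


def inverse_fourier_concatenation(features: np.ndarray, n_samples: int) -> np.ndarray:
    """Reconstruct waveforms from the 'concatenation' descriptor (no window)."""
    h = features.shape[1] // 2
    F = features[:, :h] + 1j * features[:, h:]
    return np.fft.irfft(F, n=n_samples, axis=1)
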