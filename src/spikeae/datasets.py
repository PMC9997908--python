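"""Spike waveform containers, synthetic extracellular data, and spike detection.

The synthetic generator emulates benchmark extracellular simulations: a handful
of single units with distinct spike shapes, lognormal-free Poisson firing at
0.1-2 Hz, amplitudes normally distributed and rescaled into [0.9, 2], plus one
low-amplitude (0.5) multi-unit cluster mixing 20 shapes, on a noisy background.
Spikes are 79 samples at 24 kHz and never closer than 0.3 ms.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.io import loadmat

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledSpikeSet",
    "SimulationSpec",
    "ContinuousRecording",
    "load_simulation",
    "generate_labeled_spikes",
    "generate_recording",
    "detect_spikes",
    "save_waveforms_csv",
    "load_waveforms_csv",
    "save_waveforms_npz",
    "load_waveforms_npz",
    "DEFAULT_FIELD_MAP",
]


@dataclass
class LabeledSpikeSet:
    """A matrix of fixed-length spike waveforms with optional ground truth.

    Parameters
    ----------
    waveforms : ndarray, shape (n_spikes, n_samples)
        One spike per row, amplitude in arbitrary units.
    sampling_rate : float
        Sampling rate in Hz.
    labels : ndarray of int, optional
        Ground-truth unit per spike; label 0 is reserved for the multi-unit
        (background) cluster.
    peak_indices : ndarray of int, optional
        Within-window sample index of each spike's reference peak.
    origin_indices : ndarray of int, optional
        Absolute sample index in the source signal of each window start, kept
        so windows can be re-cut from the signal (e.g. for alignment).
    source : str
        Free-text provenance tag.
    """

    waveforms: np.ndarray
    sampling_rate: float
    labels: np.ndarray | None = None
    peak_indices: np.ndarray | None = None
    origin_indices: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        if self.waveforms.ndim != 2:
            raise ValueError("waveforms must be a 2-D (n_spikes, n_samples) matrix")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = self.n_spikes
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels must have length n_spikes")
            if np.any(self.labels < 0):
                raise ValueError("labels must be non-negative (0 = multi-unit)")
        if self.peak_indices is not None:
            self.peak_indices = np.asarray(self.peak_indices, dtype=int)
            if self.peak_indices.shape != (n,):
                raise ValueError("peak_indices must have length n_spikes")
            if np.any((self.peak_indices < 0) | (self.peak_indices >= self.n_samples)):
                raise ValueError("peak_indices must lie in [0, n_samples)")
        if self.origin_indices is not None:
            self.origin_indices = np.asarray(self.origin_indices, dtype=int)
            if self.origin_indices.shape != (n,):
                raise ValueError("origin_indices must have length n_spikes")

    @property
    def n_spikes(self) -> int:
        return self.waveforms.shape[0]

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[1]

    def with_waveforms(self, waveforms: np.ndarray, **kw) -> "LabeledSpikeSet":
        """Copy of this set with new waveforms (labels etc. carried through)."""
        out = replace(self, waveforms=waveforms)
        for k, v in kw.items():
            setattr(out, k, v)
        out.__post_init__()
        return out

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_spikes


@dataclass
class SimulationSpec:
    """Parameters of the synthetic spike / recording generator.

    Defaults mirror the benchmark simulation conditions: 79-sample spikes at
    24 kHz, single-unit amplitudes rescaled into [0.9, 2], per-unit Poisson
    rates in [0.1, 2] Hz, a 0.5-amplitude multi-unit cluster of 20 shapes
    firing independently at 0.25 Hz each (5 Hz composite), and a minimum
    0.3 ms inter-spike separation.
    """

    n_single_units: int = 5
    samples_per_spike: int = 79
    sampling_rate: float = 24000.0
    amplitude_low: float = 0.9
    amplitude_high: float = 2.0
    multiunit_amplitude: float = 0.5
    multiunit_n_shapes: int = 20
    rate_low: float = 0.1
    rate_high: float = 2.0
    multiunit_unit_rate: float = 0.25
    min_separation: float = 0.0003
    duration: float = 600.0
    noise_sd: float = 0.05
    peak_jitter: int = 0

    def validate(self) -> None:
        if not self.amplitude_low < self.amplitude_high:
            raise ValueError("amplitude_low must be < amplitude_high")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if min(self.rate_low, self.rate_high, self.multiunit_unit_rate) <= 0:
            raise ValueError("all firing rates must be > 0")
        if self.samples_per_spike < 3:
            raise ValueError("samples_per_spike must be >= 3")
        if self.n_single_units < 1:
            raise ValueError("need at least one single unit")
        if self.peak_jitter < 0:
            raise ValueError("peak_jitter must be >= 0")


@dataclass
class ContinuousRecording:
    """A single-channel continuous trace with optional ground truth."""

    signal: np.ndarray
    sampling_rate: float
    true_spike_times: np.ndarray | None = None  # sample indices of peaks
    true_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float).ravel()
        if self.true_spike_times is not None:
            self.true_spike_times = np.asarray(self.true_spike_times, dtype=int)
            if np.any(np.diff(self.true_spike_times) <= 0):
                raise ValueError("true_spike_times must be strictly increasing")
        if self.true_labels is not None:
            self.true_labels = np.asarray(self.true_labels, dtype=int)
            if self.true_spike_times is None or len(self.true_labels) != len(
                self.true_spike_times
            ):
                raise ValueError("true_labels must pair with true_spike_times")


# ---------------------------------------------------------------------------
# Procedural spike templates
# ---------------------------------------------------------------------------

def _biphasic_template(
    n_samples: int,
    depol_width: float,
    repol_width: float,
    repol_depth: float,
    repol_delay: float,
    peak_frac: float = 0.5,
    peak_offset: float = 0.0,
) -> np.ndarray:
    """Parameterised biphasic action-potential shape.

    A sharp positive (depolarisation) Gaussian lobe followed by a broader
    negative (repolarisation) lobe; the lobe widths, depth and delay are the
    unit-specific knobs. The positive peak has amplitude 1 and sits near
    ``peak_frac * n_samples`` (shifted by ``peak_offset`` samples).
    """
    t = np.arange(n_samples, dtype=float)
    c = peak_frac * (n_samples - 1) + peak_offset
    pos = np.exp(-0.5 * ((t - c) / depol_width) ** 2)
    neg = repol_depth * np.exp(-0.5 * ((t - c - repol_delay) / repol_width) ** 2)
    w = pos - neg
    # renormalise so the maximum is exactly 1 at the intended peak
    return w / np.max(w)


def _unit_templates(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw one distinct template per single unit (deterministic per rng)."""
    m = spec.samples_per_spike
    out = np.empty((spec.n_single_units, m))
    for u in range(spec.n_single_units):
        out[u] = _biphasic_template(
            m,
            depol_width=rng.uniform(1.5, 4.0) * m / 79.0,
            repol_width=rng.uniform(5.0, 12.0) * m / 79.0,
            repol_depth=rng.uniform(0.3, 0.8),
            repol_delay=rng.uniform(4.0, 10.0) * m / 79.0,
        )
    return out


def _multiunit_templates(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    m = spec.samples_per_spike
    out = np.empty((spec.multiunit_n_shapes, m))
    for u in range(spec.multiunit_n_shapes):
        out[u] = _biphasic_template(
            m,
            depol_width=rng.uniform(1.5, 5.0) * m / 79.0,
            repol_width=rng.uniform(4.0, 14.0) * m / 79.0,
            repol_depth=rng.uniform(0.2, 0.9),
            repol_delay=rng.uniform(3.0, 12.0) * m / 79.0,
        )
    return out


def _rescale_amplitudes(
    draws: np.ndarray, low: float, high: float
) -> np.ndarray:
    """Min-max rescale normal draws into [low, high] (per dataset)."""
    lo, hi = draws.min(), draws.max()
    if hi == lo:
        return np.full_like(draws, 0.5 * (low + high))
    return low + (draws - lo) * (high - low) / (hi - lo)


def _jittered_template(
    spec: SimulationSpec,
    base_kwargs: dict,
    offset: int,
) -> np.ndarray:
    return _biphasic_template(spec.samples_per_spike, peak_offset=offset, **base_kwargs)


def generate_labeled_spikes(
    spec: SimulationSpec, seed: int
) -> LabeledSpikeSet:
    """Synthesize a labeled spike-waveform set.

    Per single unit: a Poisson(rate * duration) number of spikes of one
    biphasic template, amplitudes drawn from a normal distribution rescaled
    into [amplitude_low, amplitude_high]. The multi-unit cluster (label 0)
    mixes ``multiunit_n_shapes`` templates at fixed ``multiunit_amplitude``.
    Gaussian noise of sd ``noise_sd`` is added, and the peak position is
    jittered uniformly within +/- ``peak_jitter`` samples when requested.
    Bit-reproducible for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    m = spec.samples_per_spike

    # unit-specific template parameters (kept so jittered copies can be recut)
    unit_params = [
        dict(
            depol_width=rng.uniform(1.5, 4.0) * m / 79.0,
            repol_width=rng.uniform(5.0, 12.0) * m / 79.0,
            repol_depth=rng.uniform(0.3, 0.8),
            repol_delay=rng.uniform(4.0, 10.0) * m / 79.0,
        )
        for _ in range(spec.n_single_units)
    ]
    mu_params = [
        dict(
            depol_width=rng.uniform(1.5, 5.0) * m / 79.0,
            repol_width=rng.uniform(4.0, 14.0) * m / 79.0,
            repol_depth=rng.uniform(0.2, 0.9),
            repol_delay=rng.uniform(3.0, 12.0) * m / 79.0,
        )
        for _ in range(spec.multiunit_n_shapes)
    ]

    rates = rng.uniform(spec.rate_low, spec.rate_high, size=spec.n_single_units)
    counts = rng.poisson(rates * spec.duration)
    counts = np.maximum(counts, 1)  # every unit contributes at least one spike
    mu_counts = rng.poisson(
        spec.multiunit_unit_rate * spec.duration, size=spec.multiunit_n_shapes
    )

    # Normal amplitude draws, min-max rescaled into [low, high] per dataset.
    # Each unit has a characteristic mean (its distance to the electrode) with
    # a modest within-unit spread, so amplitude separates units as it does in
    # recorded data.
    unit_means = rng.normal(size=spec.n_single_units)
    draws = [
        rng.normal(loc=unit_means[u], scale=0.15, size=c)
        for u, c in enumerate(counts)
    ]
    all_draws = _rescale_amplitudes(
        np.concatenate(draws), spec.amplitude_low, spec.amplitude_high
    )
    amp_per_unit = np.split(all_draws, np.cumsum(counts)[:-1])

    waves, labels = [], []
    for u, c in enumerate(counts):
        amp = amp_per_unit[u]
        if spec.peak_jitter > 0:
            offs = rng.integers(-spec.peak_jitter, spec.peak_jitter + 1, size=c)
        else:
            offs = np.zeros(c, dtype=int)
        for a, o in zip(amp, offs):
            w = (
                _jittered_template(spec, unit_params[u], int(o))
                if o
                else _biphasic_template(m, **unit_params[u])
            )
            waves.append(a * w)
            labels.append(u + 1)
    for s, c in enumerate(mu_counts):
        if spec.peak_jitter > 0:
            offs = rng.integers(-spec.peak_jitter, spec.peak_jitter + 1, size=c)
        else:
            offs = np.zeros(c, dtype=int)
        for o in offs:
            w = (
                _jittered_template(spec, mu_params[s], int(o))
                if o
                else _biphasic_template(m, **mu_params[s])
            )
            waves.append(spec.multiunit_amplitude * w)
            labels.append(0)

    W = np.asarray(waves)
    if spec.noise_sd > 0:
        W = W + rng.normal(scale=spec.noise_sd, size=W.shape)
    labels = np.asarray(labels, dtype=int)
    peaks = np.argmax(W, axis=1)
    return LabeledSpikeSet(
        waveforms=W,
        sampling_rate=spec.sampling_rate,
        labels=labels,
        peak_indices=peaks,
        source=f"synthetic(seed={seed})",
    )


def _poisson_times(
    rate: float, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson event times in [0, duration) seconds."""
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def generate_recording(spec: SimulationSpec, seed: int) -> ContinuousRecording:
    """Synthesize a continuous trace with templates inserted at Poisson times.

    Event times are drawn per unit as independent Poisson processes and then
    thinned globally so consecutive spikes are at least ``min_separation``
    apart (earlier spike wins), matching the no-temporal-overlap construction
    of the benchmark simulations. Ground-truth peak times and labels are
    returned alongside the trace.
    """
    spec.validate()
    if spec.duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    fs = spec.sampling_rate
    m = spec.samples_per_spike
    n_total = int(round(spec.duration * fs))

    template_rng = np.random.default_rng(seed)  # same stream layout as above
    unit_t = _unit_templates(spec, template_rng)
    mu_t = _multiunit_templates(spec, template_rng)

    rates = rng.uniform(spec.rate_low, spec.rate_high, size=spec.n_single_units)
    events: list[tuple[float, int, int]] = []  # (time s, label, shape idx)
    for u in range(spec.n_single_units):
        for t in _poisson_times(rates[u], spec.duration, rng):
            events.append((t, u + 1, u))
    for s in range(spec.multiunit_n_shapes):
        for t in _poisson_times(spec.multiunit_unit_rate, spec.duration, rng):
            events.append((t, 0, s))
    events.sort()

    kept: list[tuple[float, int, int]] = []
    last = -math.inf
    for t, lab, sh in events:
        if t - last >= spec.min_separation:
            kept.append((t, lab, sh))
            last = t

    half = m // 2
    sig = (
        rng.normal(scale=spec.noise_sd, size=n_total)
        if spec.noise_sd > 0
        else np.zeros(n_total)
    )
    # per-unit characteristic amplitudes, jointly rescaled into the interval
    unit_means = rng.normal(size=spec.n_single_units)
    su_idx = [i for i, (_, lab, _) in enumerate(kept) if lab != 0]
    if su_idx:
        draws = np.array(
            [rng.normal(loc=unit_means[kept[i][2]], scale=0.15) for i in su_idx]
        )
        su_amp = dict(
            zip(su_idx, _rescale_amplitudes(draws, spec.amplitude_low, spec.amplitude_high))
        )
    else:
        su_amp = {}
    times, labels = [], []
    for i, (t, lab, sh) in enumerate(kept):
        peak = int(round(t * fs))
        start = peak - half
        if start < 0 or start + m > n_total:
            continue
        if lab == 0:
            amp, tmpl = spec.multiunit_amplitude, mu_t[sh]
        else:
            amp, tmpl = su_amp[i], unit_t[sh]
        sig[start : start + m] += amp * tmpl
        # template peak sits at floor(m/2) within the window
        times.append(start + int(np.argmax(tmpl)))
        labels.append(lab)

    if not times:
        logger.warning("no spikes placed: duration too short for requested rates")
        return ContinuousRecording(sig, fs, np.array([], dtype=int), np.array([], dtype=int))

    order = np.argsort(times)
    return ContinuousRecording(
        signal=sig,
        sampling_rate=fs,
        true_spike_times=np.asarray(times)[order],
        true_labels=np.asarray(labels)[order],
    )


# ---------------------------------------------------------------------------
# Detection front-end
# ---------------------------------------------------------------------------

def detect_spikes(
    rec: ContinuousRecording,
    band_low: float = 300.0,
    band_high: float = 7000.0,
    filter_order: int = 3,
    threshold_k: float = 4.0,
    window: int = 79,
) -> LabeledSpikeSet:
    """Band-pass filter, threshold, and cut spike windows from a recording.

    The trace is filtered forward-backward (zero phase) with a Butterworth
    band-pass, then thresholded at ``threshold_k`` standard deviations of the
    filtered signal. Each suprathreshold excursion yields one detection at its
    local maximum, with a refractory lockout of 0.3 ms; a fixed-length window
    with floor(window/2) pre-peak samples is cut around each peak. Windows
    that would cross the signal edges are skipped and counted.
    """
    fs = rec.sampling_rate
    if not (0 < band_low < band_high < fs / 2):
        raise ValueError("need 0 < band_low < band_high < sampling_rate/2")
    sos = sps.butter(
        filter_order, [band_low, band_high], btype="bandpass", fs=fs, output="sos"
    )
    filt = sps.sosfiltfilt(sos, rec.signal)
    thr = threshold_k * np.std(filt)

    lockout = max(1, int(round(0.0003 * fs)))
    above = filt > thr
    peaks = []
    i = 0
    n = len(filt)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            seg_peak = i + int(np.argmax(filt[i:j]))
            if not peaks or seg_peak - peaks[-1] >= lockout:
                peaks.append(seg_peak)
            i = j
        else:
            i += 1

    half = window // 2
    waves, kept_peaks, origins = [], [], []
    skipped = 0
    for p in peaks:
        start = p - half
        if start < 0 or start + window > n:
            skipped += 1
            continue
        waves.append(filt[start : start + window])
        kept_peaks.append(half)
        origins.append(start)
    if skipped:
        logger.info("detect_spikes: skipped %d edge spikes", skipped)

    W = np.asarray(waves) if waves else np.empty((0, window))
    return LabeledSpikeSet(
        waveforms=W,
        sampling_rate=fs,
        peak_indices=np.asarray(kept_peaks, dtype=int) if waves else np.empty(0, int),
        origin_indices=np.asarray(origins, dtype=int) if waves else np.empty(0, int),
        source="detected",
    )


# ---------------------------------------------------------------------------
# Benchmark-file and generic IO
# ---------------------------------------------------------------------------

#: Default variable names for benchmark simulation files. These follow the
#: common distribution of the public simulations (a continuous trace plus
#: ground-truth times/classes, or a pre-cut waveform matrix); actual files
#: vary, so pass your own mapping when they differ.
DEFAULT_FIELD_MAP = {
    "waveforms": "spikes",
    "labels": "spike_classes",
    "signal": "data",
    "spike_times": "spike_times",
    "sampling_rate": "sr",
    "multiunit_label": 0,
    "samples_per_spike": 79,
}


def _unwrap(arr):
    """Benchmark .mat files often wrap vectors in 1x1 cell arrays."""
    a = np.asarray(arr)
    while a.dtype == object and a.size == 1:
        a = np.asarray(a.ravel()[0])
    return a


def load_simulation(path, field_map: dict | None = None) -> LabeledSpikeSet:
    """Load a benchmark simulation file into a :class:`LabeledSpikeSet`.

    Accepts either a pre-cut waveform matrix plus labels, or a continuous
    trace plus spike times and classes, in which case fixed-length windows
    (``samples_per_spike``, default 79) are cut around each spike time.
    The multi-unit class is mapped to label 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fm = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fm.update(field_map)
    mat = loadmat(path, squeeze_me=False)

    fs = float(np.asarray(mat[fm["sampling_rate"]]).ravel()[0]) if fm[
        "sampling_rate"
    ] in mat else 24000.0

    if fm["waveforms"] in mat:
        if fm["labels"] not in mat:
            raise KeyError(
                f"file has waveforms but is missing the label variable "
                f"{fm['labels']!r}"
            )
        W = np.asarray(_unwrap(mat[fm["waveforms"]]), dtype=float)
        labels = np.asarray(_unwrap(mat[fm["labels"]]), dtype=float).ravel().astype(int)
    elif fm["signal"] in mat:
        for key in ("spike_times", "labels"):
            if fm[key] not in mat:
                raise KeyError(f"file is missing the mapped variable {fm[key]!r}")
        sig = np.asarray(_unwrap(mat[fm["signal"]]), dtype=float).ravel()
        times = np.asarray(_unwrap(mat[fm["spike_times"]]), dtype=float).ravel().astype(int)
        labels_all = (
            np.asarray(_unwrap(mat[fm["labels"]]), dtype=float).ravel().astype(int)
        )
        m = int(fm["samples_per_spike"])
        half = m // 2
        waves, labels = [], []
        skipped = 0
        for t, lab in zip(times, labels_all):
            start = t - half
            if start < 0 or start + m > len(sig):
                skipped += 1
                continue
            waves.append(sig[start : start + m])
            labels.append(lab)
        if skipped:
            logger.info("load_simulation: skipped %d out-of-bounds spikes", skipped)
        W = np.asarray(waves)
        labels = np.asarray(labels, dtype=int)
    else:
        raise KeyError(
            f"file contains neither waveform variable {fm['waveforms']!r} "
            f"nor signal variable {fm['signal']!r}"
        )

    mu = fm["multiunit_label"]
    if mu != 0:
        remapped = labels.copy()
        remapped[labels == mu] = 0
        remapped[labels == 0] = mu
        labels = remapped
    return LabeledSpikeSet(
        waveforms=W,
        sampling_rate=fs,
        labels=labels,
        peak_indices=np.argmax(W, axis=1),
        source=str(path),
    )


def save_waveforms_csv(spikes: LabeledSpikeSet, path) -> None:
    """Delimited-text waveform matrix, one spike per row, label in column 0."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        header = ["label"] + [f"s{i}" for i in range(spikes.n_samples)]
        w.writerow(header)
        labels = (
            spikes.labels
            if spikes.labels is not None
            else np.full(spikes.n_spikes, -1, dtype=int)
        )
        for lab, row in zip(labels, spikes.waveforms):
            w.writerow([int(lab)] + [repr(float(x)) for x in row])


def load_waveforms_csv(path, sampling_rate: float = 24000.0) -> LabeledSpikeSet:
    with open(path, newline="") as f:
        r = csv.reader(f)
        header = next(r)
        has_label = header and header[0] == "label"
        labels, rows = [], []
        for line in r:
            if has_label:
                labels.append(int(line[0]))
                rows.append([float(x) for x in line[1:]])
            else:
                rows.append([float(x) for x in line])
    W = np.asarray(rows)
    labs = np.asarray(labels, dtype=int) if has_label else None
    if labs is not None and np.all(labs == -1):
        labs = None
    return LabeledSpikeSet(
        waveforms=W, sampling_rate=sampling_rate, labels=labs, source=str(path)
    )


def save_waveforms_npz(spikes: LabeledSpikeSet, path) -> None:
    """Simple binary array container (numpy .npz); round-trips bit-exactly."""
    payload = {
        "waveforms": spikes.waveforms,
        "sampling_rate": np.asarray(spikes.sampling_rate),
    }
    if spikes.labels is not None:
        payload["labels"] = spikes.labels
    if spikes.peak_indices is not None:
        payload["peak_indices"] = spikes.peak_indices
    if spikes.origin_indices is not None:
        payload["origin_indices"] = spikes.origin_indices
    np.savez(path, **payload)


def load_waveforms_npz(path) -> LabeledSpikeSet:
    with np.load(path) as z:
        return LabeledSpikeSet(
            waveforms=z["waveforms"],
            sampling_rate=float(z["sampling_rate"]),
            labels=z["labels"] if "labels" in z else None,
            peak_indices=z["peak_indices"] if "peak_indices" in z else None,
            origin_indices=z["origin_indices"] if "origin_indices" in z else None,
            source=str(path),
        )
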