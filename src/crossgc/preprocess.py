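"""Segmentation, frequency-band decomposition and hemisphere partitioning.

Multichannel scalp recordings are cut into fixed overlapping windows, each
window is decomposed into the four classical EEG rhythms (theta 4-8 Hz,
alpha 8-12 Hz, beta 12-30 Hz, gamma 30-45 Hz), and the 10-20 montage is
split into 14 symmetric left/right electrode pairs with the midline
electrodes set aside.  These are the raw ingredients of every directed
connectivity measure downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal


# ---------------------------------------------------------------------------
# frequency bands

BAND_ORDER = ("theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"invalid band edges for {self.name!r}: "
                f"low={self.low_hz}, high={self.high_hz}"
            )

    @property
    def bandwidth_hz(self) -> float:
        return self.high_hz - self.low_hz


#: The four canonical rhythms, in low-to-high order.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 12.0, 30.0),
    BandSpec("gamma", 30.0, 45.0),
)


def band_by_name(name: str, bands: tuple[BandSpec, ...] = DEFAULT_BANDS) -> BandSpec:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in bands]}")


# ---------------------------------------------------------------------------
# montage

#: Symmetric left/right 10-20 electrode pairs, frontal to occipital.
CHANNEL_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"),
    ("AF3", "AF4"),
    ("F7", "F8"),
    ("F3", "F4"),
    ("FC5", "FC6"),
    ("FC1", "FC2"),
    ("T7", "T8"),
    ("C3", "C4"),
    ("CP5", "CP6"),
    ("CP1", "CP2"),
    ("P7", "P8"),
    ("P3", "P4"),
    ("PO3", "PO4"),
    ("O1", "O2"),
)

#: Electrodes on the interhemispheric axis, excluded from pairing.
MIDLINE_CHANNELS: tuple[str, ...] = ("Fz", "Cz", "Pz", "Oz")

#: The 28 paired channel names (left column then right column, pair order).
PAIRED_CHANNELS: tuple[str, ...] = tuple(
    name for pair in CHANNEL_PAIRS for name in pair
)


@dataclass(frozen=True)
class HemispherePartition:
    """Fixed split of the paired montage into left/right electrode groups."""

    left: tuple[str, ...]
    right: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]
    excluded_midline: tuple[str, ...]

    @property
    def n_per_hemisphere(self) -> int:
        return len(self.left)


def split_hemispheres(channel_names) -> HemispherePartition:
    """Partition montage names into the 14 left/right pairs.

    Any channels beyond the 28 paired ones (typically the midline
    electrodes Fz/Cz/Pz/Oz) are reported as excluded.  Missing paired
    channels are an error.
    """
    names = list(channel_names)
    missing = [n for n in PAIRED_CHANNELS if n not in names]
    if missing:
        raise ValueError(f"montage is missing paired channels: {missing}")
    used = set(PAIRED_CHANNELS)
    excluded = tuple(n for n in names if n not in used)
    left = tuple(p[0] for p in CHANNEL_PAIRS)
    right = tuple(p[1] for p in CHANNEL_PAIRS)
    return HemispherePartition(left=left, right=right, pairs=CHANNEL_PAIRS,
                               excluded_midline=excluded)


# ---------------------------------------------------------------------------
# recordings

@dataclass
class Recording:
    """A multichannel signal: channels x time matrix plus metadata."""

    channel_names: list[str]
    samples: np.ndarray
    sampling_rate_hz: float
    trial_id: str | None = None
    label: str | None = None
    window_start_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{len(self.channel_names)} channel names but "
                f"{self.samples.shape[0]} sample rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain NaN or infinite values")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.samples[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None


def segment(recording: Recording, window_s: float, hop_s: float) -> list[Recording]:
    """Cut a recording into fully contained, half-open windows.

    Windows start at 0 and advance by ``hop_s``; the count is
    floor((duration - window) / hop) + 1.
    """
    if hop_s <= 0:
        raise ValueError("hop_s must be positive")
    fs = recording.sampling_rate_hz
    win_n = round(window_s * fs)
    if win_n > recording.n_samples:
        raise ValueError(
            f"window of {window_s} s exceeds recording duration "
            f"{recording.duration_s} s"
        )
    out: list[Recording] = []
    k = 0
    while True:
        start = round(k * hop_s * fs)
        if start + win_n > recording.n_samples:
            break
        out.append(replace(
            recording,
            samples=recording.samples[:, start:start + win_n].copy(),
            window_start_s=start / fs,
        ))
        k += 1
    return out


# ---------------------------------------------------------------------------
# band extraction

@dataclass
class BandSet:
    """Per-channel band-limited components of one windowed recording."""

    channel_names: list[str]
    bands: tuple[BandSpec, ...]
    components: dict[str, np.ndarray]  # band name -> channels x time
    sampling_rate_hz: float
    trial_id: str | None = None
    label: str | None = None
    window_start_s: float = 0.0

    @property
    def n_samples(self) -> int:
        return next(iter(self.components.values())).shape[1]

    def get(self, channel: str, band: str) -> np.ndarray:
        if band not in self.components:
            raise KeyError(f"band {band!r} not present in this BandSet")
        try:
            idx = self.channel_names.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None
        return self.components[band][idx]


def design_bandpass(band: BandSpec, fs: float, n_samples: int,
                    transition_hz: float | None = None) -> np.ndarray:
    """FIR band-pass taps for zero-phase filtering.

    The filter length targets the requested transition width but is capped
    so forward-backward filtering remains feasible on short windows.
    """
    nyq = fs / 2.0
    if band.high_hz >= nyq:
        raise ValueError(
            f"band {band.name!r} upper edge {band.high_hz} Hz is at or above "
            f"the Nyquist frequency {nyq} Hz"
        )
    if transition_hz is None:
        transition_hz = 1.5
    numtaps = int(round(3.3 * nyq / transition_hz)) | 1
    cap = max(21, ((n_samples - 2) // 3) | 1)
    numtaps = min(numtaps, cap)
    return signal.firwin(numtaps, [band.low_hz, band.high_hz], fs=fs,
                         pass_zero=False)


def bandpass_zero_phase(x: np.ndarray, band: BandSpec, fs: float,
                        transition_hz: float | None = None) -> np.ndarray:
    """Zero-phase (forward-backward) FIR band-pass along the last axis."""
    taps = design_bandpass(band, fs, np.shape(x)[-1], transition_hz)
    padlen = min(3 * len(taps), np.shape(x)[-1] - 1)
    return signal.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)


def _bandpass_fft_mask(x: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    n = np.shape(x)[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
    spec = np.fft.rfft(x, axis=-1)
    return np.fft.irfft(spec * mask, n=n, axis=-1)


def extract_bands(segment: Recording,
                  bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
                  method: str = "fir",
                  transition_hz: float | None = None) -> BandSet:
    """Decompose every channel of a window into band-limited components.

    ``method="fir"`` (default) applies a zero-phase FIR band-pass per band;
    ``method="stft"`` applies a rectangular spectral mask instead.  Both are
    linear and deterministic.
    """
    fs = segment.sampling_rate_hz
    for band in bands:
        if band.high_hz >= fs / 2.0:
            raise ValueError(
                f"band {band.name!r} upper edge {band.high_hz} Hz requires a "
                f"sampling rate above {2 * band.high_hz} Hz (got {fs} Hz)"
            )
    components: dict[str, np.ndarray] = {}
    for band in bands:
        if method == "fir":
            components[band.name] = bandpass_zero_phase(
                segment.samples, band, fs, transition_hz)
        elif method == "stft":
            components[band.name] = _bandpass_fft_mask(segment.samples, band, fs)
        else:
            raise ValueError(f"unknown band-extraction method {method!r}")
    return BandSet(
        channel_names=list(segment.channel_names),
        bands=tuple(bands),
        components=components,
        sampling_rate_hz=fs,
        trial_id=segment.trial_id,
        label=segment.label,
        window_start_s=segment.window_start_s,
    )
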