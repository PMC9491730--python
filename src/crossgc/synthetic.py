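"""Labeled synthetic multichannel recordings with known directed coupling.

Each channel is a sum of four independent narrowband stochastic oscillators
(one per EEG rhythm: theta, alpha, beta, gamma) plus white sensor noise.
Directed, lagged, possibly cross-frequency and cross-hemisphere couplings
are injected at the component level: the target channel's target-band
component receives a delayed, scaled copy of the source channel's
source-band component, and a coupling can be active for a subset of class
labels only.  Ground truth is therefore exactly the quantity the
hemisphere/frequency Granger measures estimate.

A physical note on cross-band couplings: a linear lagged copy of a
source-band signal carries source-band energy, so after the broadband
mixture is re-filtered downstream, a cross-frequency coupling is visible
only through the spectral overlap of the two band filters at their shared
edge.  Adjacent band pairs (theta~alpha, alpha~beta, beta~gamma) therefore
carry a recoverable linear cross-frequency signal while distant pairs do
not -- mirroring how real cross-frequency effects concentrate at
neighbouring rhythms.  The oscillators' filter transition width (default
2 Hz) sets the size of that overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import (
    BAND_ORDER,
    DEFAULT_BANDS,
    PAIRED_CHANNELS,
    BandSet,
    BandSpec,
    Recording,
    bandpass_zero_phase,
)


@dataclass(frozen=True)
class CouplingSpec:
    """One directed, lagged, band-to-band coupling between two channels."""

    source_channel: str
    target_channel: str
    source_band: str
    target_band: str
    lag: int
    gain: float
    class_condition: tuple[str, ...] = ()  # empty = active for every label

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError(f"coupling lag must be >= 1, got {self.lag}")
        for band in (self.source_band, self.target_band):
            if band not in BAND_ORDER:
                raise ValueError(
                    f"unknown band {band!r}; expected one of {BAND_ORDER}")
        if (self.source_channel == self.target_channel
                and self.source_band == self.target_band):
            raise ValueError(
                "degenerate coupling: source and target channel and band "
                "are all identical")

    def active_for(self, label: str) -> bool:
        return not self.class_condition or label in self.class_condition


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a synthetic dataset.

    Defaults emulate a preprocessed 28-channel recording session: 128 Hz
    sampling, one-minute trials, unit-variance band oscillators and weak
    white sensor noise.
    """

    channel_names: tuple[str, ...] = PAIRED_CHANNELS
    sampling_rate_hz: float = 128.0
    trial_duration_s: float = 60.0
    n_trials_per_class: int = 5
    labels: tuple[str, ...] = ("HAHV", "LALV")
    couplings: tuple[CouplingSpec, ...] = ()
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    oscillator_transition_hz: float = 2.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        band_names = {b.name for b in self.bands}
        for c in self.couplings:
            for ch in (c.source_channel, c.target_channel):
                if ch not in self.channel_names:
                    raise ValueError(f"coupling references unknown channel {ch!r}")
            for b in (c.source_band, c.target_band):
                if b not in band_names:
                    raise ValueError(f"coupling references unknown band {b!r}")
            for lbl in c.class_condition:
                if lbl not in self.labels:
                    raise ValueError(f"coupling references unknown label {lbl!r}")

    @property
    def n_samples(self) -> int:
        return round(self.trial_duration_s * self.sampling_rate_hz)


def _delayed(x: np.ndarray, lag: int) -> np.ndarray:
    out = np.zeros_like(x)
    out[lag:] = x[:-lag]
    return out


def generate_recording(config: SynthConfig, label: str, trial_index: int = 0,
                       return_components: bool = False):
    """Generate one trial for the given class label.

    The per-trial random stream is derived deterministically from
    ``(config.seed, trial_index)``, so the same arguments always reproduce
    the same samples.  With ``return_components=True`` the ground-truth
    band components (post-coupling) are also returned as a
    :class:`~crossgc.preprocess.BandSet`.
    """
    if label not in config.labels:
        raise ValueError(f"unknown label {label!r}; config labels: {config.labels}")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(trial_index,)))
    n = config.n_samples
    fs = config.sampling_rate_hz

    comps: dict[str, np.ndarray] = {}
    n_ch = len(config.channel_names)
    for band in config.bands:
        raw = rng.standard_normal((n_ch, n))
        filt = bandpass_zero_phase(raw, band, fs,
                                   transition_hz=config.oscillator_transition_hz)
        filt /= filt.std(axis=1, keepdims=True)
        comps[band.name] = filt

    ch_index = {name: i for i, name in enumerate(config.channel_names)}
    for c in config.couplings:  # applied in list order; later couplings see earlier ones
        if not c.active_for(label):
            continue
        src = comps[c.source_band][ch_index[c.source_channel]]
        comps[c.target_band][ch_index[c.target_channel]] += (
            c.gain * _delayed(src, c.lag))

    samples = sum(comps.values()) + config.noise_sd * rng.standard_normal((n_ch, n))
    rec = Recording(
        channel_names=list(config.channel_names),
        samples=samples,
        sampling_rate_hz=fs,
        trial_id=f"{label}-{trial_index:03d}",
        label=label,
    )
    if return_components:
        bandset = BandSet(
            channel_names=list(config.channel_names),
            bands=tuple(config.bands),
            components=comps,
            sampling_rate_hz=fs,
            trial_id=rec.trial_id,
            label=label,
        )
        return rec, bandset
    return rec


def generate_dataset(config: SynthConfig) -> list[tuple[Recording, str]]:
    """Balanced labeled dataset: ``n_trials_per_class`` trials per label.

    Trial indices run globally across the dataset so every trial gets an
    independent, reproducible random stream.
    """
    out: list[tuple[Recording, str]] = []
    trial_index = 0
    for label in config.labels:
        for _ in range(config.n_trials_per_class):
            out.append((generate_recording(config, label, trial_index), label))
            trial_index += 1
    return out


def write_dataset(dataset, directory) -> None:
    """Write recordings as the CSV dialect plus a sidecar labels table."""
    import os

    from .io import write_labels_table, write_recording_csv

    os.makedirs(directory, exist_ok=True)
    entries = []
    for rec, label in dataset:
        write_recording_csv(rec, os.path.join(directory, f"{rec.trial_id}.csv"))
        entries.append((rec.trial_id, label))
    write_labels_table(entries, os.path.join(directory, "labels.tsv"))


def cc_beta_gamma_scenario(n_trials_per_class: int = 5,
                           trial_duration_s: float = 60.0,
                           gain: float = 3.0,
                           lag: int = 2,
                           seed: int = 0) -> SynthConfig:
    """Canonical two-class scenario: one strong class-conditional
    cross-hemisphere beta->gamma coupling, F3(beta) -> F4(gamma), active
    only for the HAHV class."""
    return SynthConfig(
        n_trials_per_class=n_trials_per_class,
        trial_duration_s=trial_duration_s,
        labels=("HAHV", "LALV"),
        couplings=(CouplingSpec("F3", "F4", "beta", "gamma",
                                lag=lag, gain=gain,
                                class_condition=("HAHV",)),),
        seed=seed,
    )
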