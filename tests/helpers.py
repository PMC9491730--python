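"""Shared test utilities."""

import numpy as np

from crossgc.preprocess import CHANNEL_PAIRS, HemispherePartition, Recording


def toy_partition(e: int) -> HemispherePartition:
    """Reduced montage with e electrodes per hemisphere (for count checks)."""
    pairs = CHANNEL_PAIRS[:e]
    return HemispherePartition(
        left=tuple(p[0] for p in pairs),
        right=tuple(p[1] for p in pairs),
        pairs=pairs,
        excluded_midline=(),
    )


def make_recording(n_channels=2, n_samples=512, fs=128.0, seed=0,
                   names=None) -> Recording:
    rng = np.random.default_rng(seed)
    names = names or [f"ch{i}" for i in range(n_channels)]
    return Recording(channel_names=list(names),
                     samples=rng.standard_normal((len(names), n_samples)),
                     sampling_rate_hz=fs, trial_id="t0")
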