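"""Shared test helpers."""

import numpy as np

from seqdecode.spectral import TFPower
from seqdecode.synth_eeg import Montage


def toy_tf(features, freqs=(10.0,), times=(0.0,)):
    """Wrap an (n_trials, n_electrodes) feature matrix as a 1x1 (f, t) grid."""
    n, e = features.shape
    power = features[:, :, None, None].astype(np.float64)
    power = np.broadcast_to(power, (n, e, len(freqs), len(times))).copy()
    return TFPower(
        power=power, freqs=np.asarray(freqs, float), times=np.asarray(times, float),
        valid=np.ones(len(times), bool), srate=250.0,
        montage=Montage(tuple(f"ch{i}" for i in range(e))), schedule=None,
    )
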