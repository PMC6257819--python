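"""Preprocessing and Morlet wavelet time-frequency decomposition.

Power is obtained by convolving each trial/electrode signal with a bank of
complex Morlet wavelets, w(t) = exp(2*pi*i*f*t) * exp(-t^2 / (2*sigma^2)),
where sigma = n / (2*pi*f) and the number of cycles n grows with frequency to
balance temporal against spectral precision.  Instantaneous power is the
squared magnitude of the convolved signal.  Wavelets are normalized to unit
gain at their center frequency, so a unit-amplitude sinusoid yields power 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

from .synth_eeg import EEGDataset, FRONTAL_CHANNELS


class NyquistError(ValueError):
    pass


class PaddingError(ValueError):
    pass


@dataclass(frozen=True)
class WaveletBank:
    """Log-spaced Morlet bank: frequencies, cycle counts, and widths."""

    freqs: np.ndarray
    cycles: np.ndarray
    srate: float

    @property
    def sigma(self) -> np.ndarray:
        """Gaussian width of each wavelet in seconds: sigma = n / (2*pi*f)."""
        return self.cycles / (2 * np.pi * self.freqs)

    def __len__(self):
        return self.freqs.size


def build_wavelet_bank(
    f_min: float = 4.0,
    f_max: float = 35.0,
    n_freqs: int = 32,
    n_min: float = 3.0,
    n_max: float = 10.0,
    srate: float = 250.0,
) -> WaveletBank:
    """Default bank: 32 frequencies, 4 to 35 Hz logarithmically spaced, with
    cycles interpolated linearly over the bank index from 3 to 10."""
    if not f_min < f_max:
        raise ValueError("f_min must be < f_max")
    if n_freqs < 2:
        raise ValueError("n_freqs must be >= 2")
    if f_max >= srate / 2:
        raise NyquistError(f"f_max={f_max} exceeds Nyquist ({srate / 2} Hz)")
    freqs = np.geomspace(f_min, f_max, n_freqs)
    cycles = np.linspace(n_min, n_max, n_freqs)
    return WaveletBank(freqs=freqs, cycles=cycles, srate=srate)


@dataclass
class TFPower:
    """Instantaneous power: trials x electrodes x frequencies x times (uV^2).

    ``valid`` marks time samples far enough (>= 3 sigma of the widest wavelet)
    from the epoch edges and inside the analysis window; downstream stages
    should restrict to valid samples.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray
    srate: float
    montage: object
    schedule: pd.DataFrame

    def crop_valid(self) -> "TFPower":
        """Return a view restricted to the valid time samples."""
        return TFPower(
            power=self.power[..., self.valid],
            freqs=self.freqs,
            times=self.times[self.valid],
            valid=np.ones(int(self.valid.sum()), dtype=bool),
            srate=self.srate,
            montage=self.montage,
            schedule=self.schedule,
        )


def morlet_wavelet(f: float, sigma: float, srate: float) -> np.ndarray:
    """Complex Morlet wavelet on a +/- 4 sigma support, unit center-frequency
    gain (sum of the Gaussian envelope times 2, accounting for the split of a
    real sinusoid's energy between its analytic components)."""
    half = int(np.ceil(4 * sigma * srate))
    t = np.arange(-half, half + 1) / srate
    envelope = np.exp(-(t**2) / (2 * sigma**2))
    w = envelope * np.exp(2j * np.pi * f * t)
    return 2.0 * w / envelope.sum()


def tf_power(
    eeg: EEGDataset,
    bank: WaveletBank,
    average_reference: bool = True,
    dtype=np.float32,
) -> TFPower:
    """Wavelet power for every trial, electrode, frequency, and sample.

    Convolution runs in the frequency domain (FFT, multiply, inverse FFT) per
    frequency; power is the squared magnitude of the complex output.  Epochs
    must carry at least 3 sigma of padding beyond the analysis window for the
    lowest (widest) frequency, otherwise a PaddingError is raised.
    """
    sigma_max = bank.sigma.max()
    if eeg.pad_ms < 3 * sigma_max * 1000:
        raise PaddingError(
            f"epoch padding {eeg.pad_ms} ms < 3*sigma = {3 * sigma_max * 1000:.0f} ms "
            "for the lowest bank frequency"
        )
    data = eeg.data
    if average_reference:
        data = data - data.mean(axis=1, keepdims=True)

    n_tr, n_ch, n_t = data.shape
    power = np.empty((n_tr, n_ch, len(bank), n_t), dtype=dtype)
    for k, (f, sig) in enumerate(zip(bank.freqs, bank.sigma)):
        w = morlet_wavelet(f, sig, bank.srate)
        z = sp_signal.fftconvolve(data, w[None, None, :], mode="same", axes=-1)
        power[:, :, k, :] = (z.real**2 + z.imag**2).astype(dtype)

    edge_ms = 3 * sigma_max * 1000
    valid = (
        (eeg.times >= eeg.times[0] + edge_ms)
        & (eeg.times <= eeg.times[-1] - edge_ms)
        & (eeg.times >= eeg.analysis_window[0])
        & (eeg.times <= eeg.analysis_window[1])
    )
    return TFPower(
        power=power,
        freqs=bank.freqs,
        times=eeg.times,
        valid=valid,
        srate=bank.srate,
        montage=eeg.montage,
        schedule=eeg.schedule,
    )


# ---------------------------------------------------------------------------
# Artifact rejection


class ScreeningChannelError(ValueError):
    pass


@dataclass(frozen=True)
class RejectionThresholds:
    """Sliding-window screening thresholds.

    Blink: peak-to-peak > 80 uV on the blink channels (200 ms window, 50 ms
    step).  Eye movement: a step larger than ``eye_step_uv`` between half-
    window means of the horizontal (left-right frontal) difference signal,
    stepped at 10 ms — a voltage stand-in for the 1-degree gaze criterion.
    Blocking: within-window total range <= 0.1 uV on any channel (flat line).
    """

    blink_uv: float = 80.0
    blink_window_ms: float = 200.0
    blink_step_ms: float = 50.0
    eye_step_uv: float = 40.0
    eye_window_ms: float = 200.0
    eye_step_ms: float = 10.0
    blocking_range_uv: float = 0.1
    blocking_window_ms: float = 200.0


def _sliding_starts(n_t, win, step):
    if n_t < win:
        return np.array([0])
    return np.arange(0, n_t - win + 1, step)


def reject_artifacts(
    eeg: EEGDataset,
    thresholds: RejectionThresholds = RejectionThresholds(),
    blink_channels: tuple[str, ...] = FRONTAL_CHANNELS,
    eye_pair: tuple[str, str] = ("F3", "F4"),
) -> pd.DataFrame:
    """Screen every trial; returns one row per trial with boolean columns
    ``blink``, ``eye_movement``, ``blocking`` and ``rejected`` (any rule)."""
    names = eeg.montage.names
    for ch in blink_channels + eye_pair:
        if ch not in names:
            raise ScreeningChannelError(f"screening channel {ch!r} not in montage")
    bl_ix = [eeg.montage.index(c) for c in blink_channels]
    l_ix, r_ix = (eeg.montage.index(c) for c in eye_pair)

    sr = eeg.srate
    ms = lambda x: max(1, int(round(x * sr / 1000.0)))
    n_tr, _, n_t = eeg.data.shape

    th = thresholds
    blink = np.zeros(n_tr, dtype=bool)
    eye = np.zeros(n_tr, dtype=bool)
    blocking = np.zeros(n_tr, dtype=bool)

    win_b, step_b = ms(th.blink_window_ms), ms(th.blink_step_ms)
    win_e, step_e = ms(th.eye_window_ms), ms(th.eye_step_ms)
    win_k = ms(th.blocking_window_ms)

    horiz = eeg.data[:, l_ix, :] - eeg.data[:, r_ix, :]
    for s in _sliding_starts(n_t, win_b, step_b):
        seg = eeg.data[:, bl_ix, s : s + win_b]
        blink |= (seg.max(axis=2) - seg.min(axis=2) > th.blink_uv).any(axis=1)
    half = win_e // 2
    for s in _sliding_starts(n_t, win_e, step_e):
        seg = horiz[:, s : s + win_e]
        step_size = np.abs(seg[:, half:].mean(axis=1) - seg[:, :half].mean(axis=1))
        eye |= step_size > th.eye_step_uv
    # blocking: rolling range over a 200 ms window at every alignment
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    rng_roll = (
        maximum_filter1d(eeg.data, size=win_k, axis=-1, mode="nearest")
        - minimum_filter1d(eeg.data, size=win_k, axis=-1, mode="nearest")
    )
    half_k = win_k // 2
    interior = rng_roll[:, :, half_k : n_t - half_k]
    blocking |= (interior <= th.blocking_range_uv).any(axis=(1, 2))

    report = pd.DataFrame(
        {
            "trial": np.arange(n_tr),
            "blink": blink,
            "eye_movement": eye,
            "blocking": blocking,
        }
    )
    report["rejected"] = report[["blink", "eye_movement", "blocking"]].any(axis=1)
    return report


# ---------------------------------------------------------------------------
# Univariate band-power contrasts


def band_power(
    tf: TFPower,
    electrodes,
    band: tuple[float, float],
    window: tuple[float, float],
) -> np.ndarray:
    """Mean power per trial over named electrodes, a frequency band, and a
    time window (valid samples only)."""
    e_ix = [tf.montage.index(c) for c in electrodes]
    f_sel = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
    t_sel = (tf.times >= window[0]) & (tf.times <= window[1]) & tf.valid
    if not f_sel.any() or not t_sel.any():
        raise ValueError("band/window selects no computed samples")
    block = tf.power[:, e_ix][:, :, f_sel][:, :, :, t_sel]
    return block.mean(axis=(1, 2, 3))


def band_power_contrast(
    tf_by_subject: list[TFPower],
    labels_by_subject: list[np.ndarray],
    electrodes=("Fz", "Cz"),
    band: tuple[float, float] = (4.0, 7.0),
    window: tuple[float, float] = (-600.0, 0.0),
) -> dict:
    """Paired contrast of mean band power: within-chunk position 1 versus
    positions 2 and 3, at named electrodes (mid-frontal theta by default).

    Returns the group mean difference b, its SE, t, p (two-sided) and the
    per-subject differences.
    """
    diffs = []
    for tf, labels in zip(tf_by_subject, labels_by_subject):
        bp = band_power(tf, electrodes, band, window)
        labels = np.asarray(labels)
        m1 = bp[labels == 1].mean() if (labels == 1).any() else np.nan
        m23 = bp[labels != 1].mean() if (labels != 1).any() else np.nan
        if np.isnan(m1) or np.isnan(m23):
            raise ValueError("empty condition cell in band_power_contrast")
        diffs.append(m1 - m23)
    diffs = np.asarray(diffs)
    n = diffs.size
    b = diffs.mean()
    if n > 1 and np.ptp(diffs) > 0:
        se = diffs.std(ddof=1) / np.sqrt(n)
        t = b / se
        p = 2 * stats.t.sf(abs(t), n - 1)
    else:
        se, t, p = 0.0, 0.0 if b == 0 else np.inf, 1.0
    return {"b": b, "se": se, "t": t, "p": p, "subject_diffs": diffs}
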