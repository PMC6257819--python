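"""Synthetic oscillatory EEG with known, injectable control-code patterns.

The generator builds multichannel epochs as 1/f-shaped background noise plus
band-limited oscillations whose *spatial pattern* (topography across
electrodes) depends on the trial's control-code instance.  Decoding stages can
then be validated by recovery: a code injected in a given band and time window
must be decodable there and nowhere else.

Conventions: amplitudes in microvolts, times in milliseconds with 0 at probe
onset, sampling at 250 Hz.  Epochs carry symmetric padding beyond the analysis
window so that wavelet convolution edge effects never touch analyzed samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default 20-channel montage (10/20 sites plus posterior intermediates).
DEFAULT_CHANNELS = (
    "F3", "Fz", "F4", "T3", "C3", "Cz", "C4", "T4", "P3", "Pz",
    "P4", "T5", "T6", "O1", "O2", "OL", "OR", "PO3", "PO4", "POz",
)

FRONTAL_CHANNELS = ("F3", "Fz", "F4")

#: Canonical frequency bands (Hz).
THETA = (4.0, 7.0)
ALPHA = (8.0, 12.0)

#: Canonical analysis periods (ms relative to probe onset).
PREP = (-600.0, 0.0)
PROBE = (0.0, 300.0)


@dataclass(frozen=True)
class Montage:
    names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("electrode names must be unique")

    def __len__(self):
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


class PatternSpecError(ValueError):
    """A schedule label has no matching topography."""


def make_topographies(
    labels,
    n_channels: int,
    rng: np.random.Generator,
    min_angle_deg: float = 30.0,
    max_tries: int = 2000,
) -> dict:
    """Unit-norm random topographies, one per label, pairwise separated.

    Vectors are drawn standard normal and unit-normalized; the draw is
    rejected until every pair subtends at least ``min_angle_deg`` so that
    separability is controlled by amplitude, not chance geometry.
    """
    labels = list(labels)
    cos_max = np.cos(np.deg2rad(min_angle_deg))
    for _ in range(max_tries):
        vecs = rng.standard_normal((len(labels), n_channels))
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        gram = np.abs(vecs @ vecs.T)
        np.fill_diagonal(gram, 0.0)
        if gram.max() <= cos_max:
            return {lab: vecs[i] for i, lab in enumerate(labels)}
    raise RuntimeError("could not find well-separated topographies")


@dataclass(frozen=True)
class CodePatternSpec:
    """How one control code is written into the signal.

    ``code`` names a schedule column (element, within_chunk_position,
    chunk_identity, chunk_position).  Every instance of the code gets its own
    topography; the oscillation is a sinusoid at the band center with per-trial
    frequency jitter and random phase, confined to ``window`` with smooth
    cosine ramps.
    """

    code: str
    band: tuple[float, float]
    window: tuple[float, float]
    amplitude: float
    topographies: dict | None = None
    freq_jitter: float = 1.0
    ramp_ms: float = 50.0

    def __post_init__(self):
        f_lo, f_hi = self.band
        if not (f_lo < f_hi):
            raise ValueError("band must satisfy f_lo < f_hi")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    @property
    def center_freq(self) -> float:
        return 0.5 * (self.band[0] + self.band[1])


@dataclass(frozen=True)
class NoiseSpec:
    """Background noise: 1/f^beta spectral shape, per-channel SD in uV, and a
    common-mode channel correlation."""

    one_over_f_exponent: float = 1.0
    noise_sd: float = 10.0
    channel_correlation: float = 0.0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.channel_correlation < 1.0:
            raise ValueError("channel_correlation must be in [0, 1)")


@dataclass
class EEGDataset:
    """Epoched multichannel data: trials x electrodes x samples (uV)."""

    data: np.ndarray
    srate: float
    times: np.ndarray  # ms, 0 = probe onset
    montage: Montage
    schedule: pd.DataFrame
    analysis_window: tuple[float, float] = (-1250.0, 700.0)
    pad_ms: float = 400.0

    def __post_init__(self):
        if self.data.shape[2] != self.times.size:
            raise ValueError("times axis does not match data")
        if self.data.shape[1] != len(self.montage):
            raise ValueError("montage does not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EEGDataset":
        return EEGDataset(
            data=self.data.copy(),
            srate=self.srate,
            times=self.times.copy(),
            montage=self.montage,
            schedule=self.schedule,
            analysis_window=self.analysis_window,
            pad_ms=self.pad_ms,
        )


def _one_over_f_noise(rng, shape, exponent, srate):
    """White noise spectrally shaped to 1/f^exponent, unit variance."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / srate)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * shaping, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _window_envelope(times, t0, t1, ramp_ms):
    """Smooth on/off envelope: 1 inside [t0, t1], cosine ramps at the edges."""
    env = np.zeros_like(times, dtype=float)
    inside = (times >= t0) & (times <= t1)
    env[inside] = 1.0
    if ramp_ms > 0:
        on = (times >= t0 - ramp_ms) & (times < t0)
        env[on] = 0.5 * (1 + np.cos(np.pi * (t0 - times[on]) / ramp_ms))
        off = (times > t1) & (times <= t1 + ramp_ms)
        env[off] = 0.5 * (1 + np.cos(np.pi * (times[off] - t1) / ramp_ms))
    return env


def simulate_dataset(
    schedule: pd.DataFrame,
    patterns: list[CodePatternSpec],
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    srate: float = 250.0,
    analysis_window: tuple[float, float] = (-1250.0, 700.0),
    pad_ms: float = 400.0,
    montage: Montage = Montage(),
    chaining_drift: float = 0.0,
) -> EEGDataset:
    """Simulate an epoched EEG dataset for one subject's schedule.

    Each trial is background noise plus, for every pattern spec, a windowed
    band-limited oscillation scaled by the topography of that trial's code
    instance.  ``chaining_drift`` in (0, 1] morphs element topographies toward
    the *next* within-chunk element's topography during the second half of
    blocks, emulating the anticipatory drift predicted by associative-chaining
    accounts (0 = stationary patterns).

    Bit-reproducible for a fixed seed.
    """
    if schedule.empty:
        raise ValueError("schedule is empty")
    rng = np.random.default_rng(seed)
    n_tr = len(schedule)
    n_ch = len(montage)
    t0 = analysis_window[0] - pad_ms
    t1 = analysis_window[1] + pad_ms
    step = 1000.0 / srate
    times = np.arange(np.round(t0 / step), np.round(t1 / step) + 1) * step

    data = _one_over_f_noise(
        rng, (n_tr, n_ch, times.size), noise.one_over_f_exponent, srate
    )
    if noise.channel_correlation > 0:
        common = _one_over_f_noise(
            rng, (n_tr, 1, times.size), noise.one_over_f_exponent, srate
        )
        rho = noise.channel_correlation
        data = np.sqrt(1 - rho) * data + np.sqrt(rho) * common
    data *= noise.noise_sd

    # Pre-resolve topographies (seeded) for specs that did not supply any.
    resolved = []
    for spec in patterns:
        labels = schedule[spec.code].unique()
        labels = sorted(labels, key=str)
        topo = spec.topographies
        if topo is None:
            topo = make_topographies(labels, n_ch, rng)
        missing = [lab for lab in labels if lab not in topo]
        if missing:
            raise PatternSpecError(
                f"code {spec.code!r}: no topography for instance(s) {missing}"
            )
        resolved.append(replace(spec, topographies=topo))

    half_block = schedule["block"].median() if "block" in schedule else 0.0
    next_element = _next_within_chunk_element(schedule)

    tsec = times / 1000.0
    for spec in resolved:
        env = _window_envelope(times, spec.window[0], spec.window[1], spec.ramp_ms)
        if spec.amplitude == 0 or env.max() == 0:
            # still consume the trial RNG stream for reproducibility symmetry
            rng.random((n_tr, 2))
            continue
        f_trial = spec.center_freq + rng.uniform(-spec.freq_jitter, spec.freq_jitter, n_tr)
        phase = rng.uniform(0, 2 * np.pi, n_tr)
        carriers = np.sin(2 * np.pi * f_trial[:, None] * tsec[None, :] + phase[:, None])
        carriers *= env[None, :] * spec.amplitude
        labels = schedule[spec.code].to_numpy()
        topos = np.stack([spec.topographies[lab] for lab in labels])  # (n_tr, n_ch)
        if chaining_drift > 0 and spec.code == "element":
            late = (schedule["block"].to_numpy() > half_block)
            for i in np.flatnonzero(late):
                nxt = next_element[i]
                if nxt is not None:
                    t_next = spec.topographies[nxt]
                    v = (1 - chaining_drift) * topos[i] + chaining_drift * t_next
                    topos[i] = v / np.linalg.norm(v)
        data += topos[:, :, None] * carriers[:, None, :]

    snrs = {
        spec.code: spec.amplitude / (np.sqrt(2) * noise.noise_sd)
        for spec in resolved
    }
    logger.info("simulated %d trials x %d ch; pattern RMS/noise-SD ratios: %s",
                n_tr, n_ch, snrs)

    return EEGDataset(
        data=data,
        srate=srate,
        times=times,
        montage=montage,
        schedule=schedule.reset_index(drop=True),
        analysis_window=analysis_window,
        pad_ms=pad_ms,
    )


def _next_within_chunk_element(schedule: pd.DataFrame):
    """For each trial, the next element if it stays within the same chunk."""
    elements = schedule["element"].to_numpy()
    wpos = schedule["within_chunk_position"].to_numpy()
    out: list = [None] * len(schedule)
    for i in range(len(schedule) - 1):
        if wpos[i + 1] == wpos[i] + 1:
            out[i] = elements[i + 1]
    return out


@dataclass(frozen=True)
class BehaviorParams:
    """Generative parameters for single-trial behavior.

    RTs are log-normal around a position-dependent location: ``rt_base`` plus
    ``boundary_cost`` at within-chunk position 1 (the chunk-boundary effect).
    Error probability is ``error_base`` plus ``boundary_error_cost`` at
    position 1.  For subjects labeled low-WM, both boundary effects are
    multiplied by ``wm_group_scaling``.  ``evidence_coupling`` adds a linear
    term on the log-RT scale for a supplied per-trial evidence variable.
    """

    rt_base: float = 480.0
    boundary_cost: float = 14.0
    error_base: float = 0.06
    boundary_error_cost: float = 0.038
    wm_group_scaling: float = 1.0
    evidence_coupling: float = 0.0
    rt_sd: float = 0.15
    retrieval_base: float = 1200.0
    retrieval_boundary_cost: float = 372.0
    retrieval_sd: float = 0.45

    def __post_init__(self):
        for name in ("error_base", "boundary_error_cost"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def simulate_behavior(
    schedule: pd.DataFrame,
    params: BehaviorParams = BehaviorParams(),
    seed: int = 0,
    variant: str = "exp1",
    wm_group: str = "high",
    evidence: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate RT / accuracy (and exp2 self-paced retrieval time) per trial.

    The multiplicative log-normal noise is mean-one, so the expected RT
    contrast between position 1 and positions 2/3 equals ``boundary_cost``
    exactly and parameter-recovery tests can target the generator truth.
    """
    rng = np.random.default_rng(seed)
    n = len(schedule)
    is_boundary = (schedule["within_chunk_position"].to_numpy() == 1).astype(float)
    scale = params.wm_group_scaling if wm_group == "low" else 1.0

    mu = params.rt_base + scale * params.boundary_cost * is_boundary
    log_rt = np.log(mu) + params.rt_sd * rng.standard_normal(n) - params.rt_sd**2 / 2
    if evidence is not None:
        ev = np.asarray(evidence, dtype=float)
        ev = ev - ev.mean()
        log_rt = log_rt + params.evidence_coupling * ev
    rt = np.exp(log_rt)

    p_err = np.clip(
        params.error_base + scale * params.boundary_error_cost * is_boundary, 0, 1
    )
    correct = rng.random(n) >= p_err

    out = schedule.reset_index(drop=True).copy()
    out["rt"] = rt
    out["correct"] = correct
    if variant == "exp2":
        mu_r = params.retrieval_base + scale * params.retrieval_boundary_cost * is_boundary
        out["retrieval_time"] = np.exp(
            np.log(mu_r)
            + params.retrieval_sd * rng.standard_normal(n)
            - params.retrieval_sd**2 / 2
        )
    return out


@dataclass(frozen=True)
class ArtifactSpec:
    """Rates and magnitudes of injectable artifacts."""

    blink_rate: float = 0.0
    blink_amp: float = 100.0
    blink_dur_ms: float = 300.0
    flat_rate: float = 0.0
    flat_dur_ms: float = 200.0

    def __post_init__(self):
        for name in ("blink_rate", "flat_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def inject_artifacts(
    eeg: EEGDataset, spec: ArtifactSpec, seed: int = 0
) -> tuple[EEGDataset, pd.DataFrame]:
    """Insert blink-like deflections and flat ("blocking") segments.

    Blinks are frontal-weighted Gaussian bumps (~300 ms); flats replace a
    segment with its mean on all channels.  Returns a new dataset plus the
    ground-truth mask (one row per trial: blink, flat).  With both rates zero
    the returned data equal the input bit for bit.
    """
    rng = np.random.default_rng(seed)
    out = eeg.copy()
    n_tr, n_ch, n_t = out.data.shape
    blink = rng.random(n_tr) < spec.blink_rate
    flat = rng.random(n_tr) < spec.flat_rate

    ch_weights = np.full(n_ch, 0.2)
    for name in FRONTAL_CHANNELS:
        if name in eeg.montage.names:
            ch_weights[eeg.montage.index(name)] = 1.0

    t_lo, t_hi = eeg.analysis_window
    for i in np.flatnonzero(blink):
        center = rng.uniform(t_lo + spec.blink_dur_ms, t_hi - spec.blink_dur_ms)
        sigma = spec.blink_dur_ms / 6.0
        bump = spec.blink_amp * np.exp(-0.5 * ((eeg.times - center) / sigma) ** 2)
        out.data[i] += ch_weights[:, None] * bump[None, :]
    for i in np.flatnonzero(flat):
        start = rng.uniform(t_lo, t_hi - spec.flat_dur_ms)
        sel = (eeg.times >= start) & (eeg.times <= start + spec.flat_dur_ms)
        out.data[i][:, sel] = out.data[i][:, sel].mean(axis=1, keepdims=True)

    mask = pd.DataFrame({"trial": np.arange(n_tr), "blink": blink, "flat": flat})
    return out, mask
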