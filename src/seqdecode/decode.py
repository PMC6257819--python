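"""Frequency-by-time multivariate decoding of control codes.

An independent linear classifier is trained at every (frequency, time) cell of
the wavelet power representation.  The pipeline follows a fold-matrix design:
trials are partitioned into k folds with per-class counts equated by random
dropping; within each fold, power is averaged over trials per class and
electrode after smoothing with a centered 100-ms (25-sample) sliding window;
each fold's class-by-electrode matrix is z-scored across electrodes per
(class, frequency, time) cell to remove spatially uniform effects.  A
shrinkage-regularized linear discriminant is trained on k-1 folds' class rows
and tested on the held-out fold's rows; folds rotate, the whole partition is
redrawn for a configurable number of iterations, and accuracies, confusion
counts, and per-trial posteriors are averaged over everything.

Chance level for the three-instance control codes is 1/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .spectral import TFPower


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class DecodeConfig:
    """Cross-validation and windowing settings.

    ``window_step`` (samples) decimates the time axis of the decoded map;
    1 decodes every sample.  ``shrinkage`` is passed to the discriminant
    ("auto" = analytic Ledoit-Wolf shrinkage of the within-class covariance).
    """

    n_folds: int = 4
    n_iterations: int = 30
    window_samples: int = 25
    window_step: int = 1
    shrinkage: str | float = "auto"
    seed: int = 0
    compute_evidence: bool = True

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.window_samples < 1:
            raise ValueError("window_samples must be >= 1")


@dataclass
class DecodeResult:
    """Frequency-by-time decoding output for one subject and one code."""

    accuracy: np.ndarray            # (f, t)
    confusion: np.ndarray           # (f, t, predicted, true); true columns sum to 1
    evidence: np.ndarray | None     # (trials, f, t) mean logit P(correct), NaN if untested
    trial_accuracy: np.ndarray | None  # (trials, f, t) mean correct indicator
    freqs: np.ndarray
    times: np.ndarray
    classes: np.ndarray
    chance: float

    def mean_confusion(self, band, period) -> np.ndarray:
        """Confusion matrix averaged over a band/period rectangle, columns
        (true classes) renormalized to 1."""
        sel_f = (self.freqs >= band[0]) & (self.freqs <= band[1])
        sel_t = (self.times >= period[0]) & (self.times <= period[1])
        if not sel_f.any() or not sel_t.any():
            raise ValueError("empty band/period selection")
        m = self.confusion[sel_f][:, sel_t].mean(axis=(0, 1))
        return m / m.sum(axis=0, keepdims=True)


def make_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random k-fold partition with per-class counts equated within and across
    folds by randomly dropping surplus trials (dropped trials get fold -1)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    q = counts.min() // n_folds
    if q < 1:
        short = classes[np.argmin(counts)]
        raise InsufficientDataError(
            f"class {short!r} has {counts.min()} trials, fewer than {n_folds} folds"
        )
    fold = np.full(labels.size, -1, dtype=int)
    for c in classes:
        ix = np.flatnonzero(labels == c)
        rng.shuffle(ix)
        keep = ix[: q * n_folds]
        fold[keep] = np.repeat(np.arange(n_folds), q)
    return fold


def window_average(power: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving average along the last (time) axis."""
    if window_samples == 1:
        return power
    return uniform_filter1d(power, size=window_samples, axis=-1, mode="nearest")


def zscore_across(x: np.ndarray, axis: int) -> np.ndarray:
    """Z-score along ``axis`` with population SD; constant cells map to 0."""
    m = x.mean(axis=axis, keepdims=True)
    s = x.std(axis=axis, keepdims=True)
    safe = np.where(s == 0, 1.0, s)
    return (x - m) / safe


def fold_average(
    power_w: np.ndarray, fold: np.ndarray, labels: np.ndarray, classes: np.ndarray,
    n_folds: int,
) -> np.ndarray:
    """Trial-average per (fold, class), then z-score across electrodes per
    (fold, class, frequency, time).  Input (trials, e, f, t) already window-
    smoothed; output (folds, classes, e, f, t)."""
    _, n_e, n_f, n_t = power_w.shape
    F = np.empty((n_folds, classes.size, n_e, n_f, n_t), dtype=power_w.dtype)
    for r in range(n_folds):
        for ci, c in enumerate(classes):
            sel = (fold == r) & (labels == c)
            F[r, ci] = power_w[sel].mean(axis=0)
    return zscore_across(F, axis=2)


def _logit(p, clip=1e-6):
    p = np.clip(p, clip, 1 - clip)
    return np.log(p / (1 - p))


def _select_times(tf: TFPower, step: int):
    ix = np.flatnonzero(tf.valid)[::step]
    return ix


def decode_map(tf: TFPower, labels, config: DecodeConfig = DecodeConfig()) -> DecodeResult:
    """Train and test an LDA at every (frequency, time) cell.

    Per-trial posteriors (``evidence``) come from applying each fold's trained
    classifier to the held-out fold's single trials (window-smoothed and
    z-scored across electrodes per trial), averaged over iterations.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise InsufficientDataError("decoding needs >= 2 classes")
    rng = np.random.default_rng(config.seed)

    t_ix = _select_times(tf, config.window_step)
    pw = window_average(tf.power, config.window_samples)[..., t_ix]
    n_tr, n_e, n_f, n_t = pw.shape
    class_ix = {c: i for i, c in enumerate(classes)}
    y_true_ix = np.array([class_ix[c] for c in labels])

    if config.compute_evidence:
        Z = zscore_across(pw, axis=1)  # per-trial electrode z-scores
        evid_sum = np.zeros((n_tr, n_f, n_t))
        evid_cnt = np.zeros((n_tr, n_f, n_t))
        tacc_sum = np.zeros((n_tr, n_f, n_t))

    acc = np.zeros((n_f, n_t))
    conf = np.zeros((n_f, n_t, classes.size, classes.size))
    n_tests = 0

    y_train = np.tile(np.arange(classes.size), config.n_folds - 1)
    for _ in range(config.n_iterations):
        fold = make_folds(labels, config.n_folds, rng)
        F = fold_average(pw, fold, labels, classes, config.n_folds)
        for fi in range(n_f):
            for ti in range(n_t):
                cell = F[:, :, :, fi, ti]  # (k, c, e)
                for r in range(config.n_folds):
                    X_train = np.concatenate(
                        [cell[s] for s in range(config.n_folds) if s != r]
                    )
                    clf = LinearDiscriminantAnalysis(
                        solver="lsqr", shrinkage=config.shrinkage
                    )
                    clf.fit(X_train, y_train)
                    pred = clf.predict(cell[r])
                    acc[fi, ti] += np.mean(pred == np.arange(classes.size))
                    conf[fi, ti, pred, np.arange(classes.size)] += 1
                    if config.compute_evidence:
                        sel = np.flatnonzero(fold == r)
                        proba = clf.predict_proba(Z[sel, :, fi, ti])
                        evid_sum[sel, fi, ti] += _logit(
                            proba[np.arange(sel.size), y_true_ix[sel]]
                        )
                        evid_cnt[sel, fi, ti] += 1
                        tacc_sum[sel, fi, ti] += (
                            proba.argmax(axis=1) == y_true_ix[sel]
                        )
        n_tests += config.n_folds

    acc /= n_tests
    conf /= conf.sum(axis=2, keepdims=True)

    evidence = trial_acc = None
    if config.compute_evidence:
        with np.errstate(invalid="ignore"):
            evidence = np.where(evid_cnt > 0, evid_sum / np.maximum(evid_cnt, 1), np.nan)
            trial_acc = np.where(evid_cnt > 0, tacc_sum / np.maximum(evid_cnt, 1), np.nan)

    return DecodeResult(
        accuracy=acc,
        confusion=conf,
        evidence=evidence,
        trial_accuracy=trial_acc,
        freqs=tf.freqs,
        times=tf.times[t_ix],
        classes=classes,
        chance=1.0 / classes.size,
    )


def summarize_period(
    values: np.ndarray,
    freqs: np.ndarray,
    times: np.ndarray,
    band: tuple[float, float],
    period: tuple[float, float],
) -> float:
    """Mean over the rectangle of (frequency, time) cells in ``band`` x
    ``period``; ``values``' last two axes must be (f, t)."""
    sel_f = (freqs >= band[0]) & (freqs <= band[1])
    sel_t = (times >= period[0]) & (times <= period[1])
    if not sel_f.any() or not sel_t.any():
        raise ValueError("band/period selects no cells")
    return float(np.nanmean(values[..., sel_f, :][..., sel_t]))


def decode_conditional(
    tf: TFPower,
    labels,
    condition_labels,
    config: DecodeConfig = DecodeConfig(),
    mode: str = "train_all",
) -> dict:
    """Decode ``labels`` separately per stratum of ``condition_labels``.

    mode "train_all": one classifier set trained on all trials; per-stratum
    accuracy maps are means of held-out single-trial correctness within the
    stratum.  mode "within": decoding re-run independently on each stratum's
    trials.  Empty strata are skipped with a warning.
    """
    condition_labels = np.asarray(condition_labels)
    strata = np.unique(condition_labels)
    out = {}
    if mode == "train_all":
        cfg = DecodeConfig(**{**config.__dict__, "compute_evidence": True})
        res = decode_map(tf, labels, cfg)
        for s in strata:
            sel = condition_labels == s
            if not sel.any():
                warnings.warn(f"stratum {s!r} empty; skipped", stacklevel=2)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                acc = np.nanmean(res.trial_accuracy[sel], axis=0)
            out[s] = DecodeResult(
                accuracy=acc,
                confusion=res.confusion,
                evidence=None,
                trial_accuracy=None,
                freqs=res.freqs,
                times=res.times,
                classes=res.classes,
                chance=res.chance,
            )
    elif mode == "within":
        for s in strata:
            sel = condition_labels == s
            if not sel.any():
                warnings.warn(f"stratum {s!r} empty; skipped", stacklevel=2)
                continue
            tf_s = TFPower(
                power=tf.power[sel],
                freqs=tf.freqs,
                times=tf.times,
                valid=tf.valid,
                srate=tf.srate,
                montage=tf.montage,
                schedule=tf.schedule.iloc[sel].reset_index(drop=True)
                if tf.schedule is not None
                else None,
            )
            out[s] = decode_map(tf_s, np.asarray(labels)[sel], config)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def band_period_features(
    tf: TFPower, band: tuple[float, float], period: tuple[float, float],
    window_samples: int = 25,
) -> np.ndarray:
    """Per-trial electrode feature vectors: power averaged over a frequency
    band and time period (the reduced representation used for generalization,
    similarity, and brain-behavior analyses)."""
    sel_f = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
    sel_t = (tf.times >= period[0]) & (tf.times <= period[1]) & tf.valid
    if not sel_f.any() or not sel_t.any():
        raise ValueError("band/period selects no cells")
    pw = window_average(tf.power, window_samples)
    return pw[:, :, sel_f][:, :, :, sel_t].mean(axis=(2, 3))
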