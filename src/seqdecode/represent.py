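"""Representational analyses: generalization, model-matrix RSA, chaining.

Three complementary probes of what the decodable signal represents:

* cross-classification (does a position decoder trained on some elements
  transfer to a held-out element?), scored against size-matched reference
  sets so the comparison is estimator-fair;
* representational similarity analysis regressing logit-transformed decoder
  confusion frequencies on theoretical model matrices entered simultaneously
  in a hierarchical model;
* the chaining-asymmetry test, which asks whether the spatial pattern of an
  element late in training drifts toward its successor's pattern
  (cor(A_late, B_early) > cor(A_early, B_late) under associative chaining).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .decode import DecodeConfig, band_period_features, make_folds, zscore_across
from .spectral import TFPower
from .task_model import ELEMENTS

MODEL_KINDS = (
    "discrete",
    "unique_position_1",
    "element9",
    "position9",
    "conjunction9",
    "elem_n_minus_1",
    "elem_n",
    "conjunction_lag",
)


@dataclass(frozen=True)
class ModelMatrix:
    """Theoretical confusion structure: values[predicted, true], columns
    (true classes) sum to 1."""

    kind: str
    values: np.ndarray
    class_labels: tuple

    def __post_init__(self):
        colsums = self.values.sum(axis=0)
        if not np.allclose(colsums, 1.0):
            raise ValueError(f"model {self.kind!r} columns do not sum to 1")


def _pair_classes():
    return tuple((a, b) for a, b in itertools.product(ELEMENTS, ELEMENTS) if a != b)


def build_model_matrix(kind: str, n_classes: int = 3) -> ModelMatrix:
    """Construct one of the built-in theoretical confusion models.

    discrete: perfect classification (identity).  unique_position_1: position
    1 fully distinct, positions 2 and 3 mutually confusable (0.5 each).
    element9 / position9 / conjunction9: over the 9 element-x-position
    classes, confusions spread 1/3 among same-element (resp. same-position)
    cells, or identity for the full conjunction.  elem_n_minus_1 / elem_n /
    conjunction_lag: over the 6 non-repeating (previous, current) element
    pairs, 0.5 among cells sharing the modeled attribute, or identity.
    """
    if kind == "discrete":
        labels = tuple(range(1, n_classes + 1))
        vals = np.eye(n_classes)
    elif kind == "unique_position_1":
        labels = (1, 2, 3)
        vals = np.array([[1, 0, 0], [0, 0.5, 0.5], [0, 0.5, 0.5]])
    elif kind in ("element9", "position9", "conjunction9"):
        labels = tuple(itertools.product(ELEMENTS, (1, 2, 3)))
        if kind == "conjunction9":
            vals = np.eye(9)
        else:
            attr = 0 if kind == "element9" else 1
            vals = np.array(
                [[1 / 3 if li[attr] == lj[attr] else 0 for lj in labels] for li in labels]
            )
    elif kind in ("elem_n_minus_1", "elem_n", "conjunction_lag"):
        labels = _pair_classes()
        if kind == "conjunction_lag":
            vals = np.eye(6)
        else:
            attr = 0 if kind == "elem_n_minus_1" else 1
            vals = np.array(
                [[0.5 if li[attr] == lj[attr] else 0 for lj in labels] for li in labels]
            )
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return ModelMatrix(kind=kind, values=vals, class_labels=labels)


@dataclass
class RSAFit:
    """Simultaneous hierarchical regression of confusions on model matrices."""

    coefficients: dict  # kind -> {"b", "se", "t"}
    method: str         # "mixed" or "two_stage"
    n_subjects: int


class CollinearModelError(ValueError):
    pass


def fit_rsa(
    confusions: np.ndarray,
    models: list[ModelMatrix],
    clip: float = 1e-4,
    standardize: bool = False,
) -> RSAFit:
    """Fit model matrices simultaneously to subject-level confusion matrices.

    ``confusions`` is (subjects, predicted, true) of relative frequencies
    (columns sum to 1).  All cells, including the diagonal, are
    logit-transformed (clipped at ``clip``) and regressed on the flattened
    model predictors with fixed effects plus per-subject random intercepts
    and slopes; if the mixed fit does not converge, a two-stage fallback
    (per-subject least squares, then one-sample t on the coefficients) is
    used and recorded in ``method``.
    """
    confusions = np.asarray(confusions, dtype=float)
    if confusions.ndim != 3:
        raise ValueError("confusions must be (subjects, predicted, true)")
    n_sub = confusions.shape[0]
    if n_sub < 2:
        raise ValueError("need >= 2 subjects")
    m = confusions.shape[1]
    for mod in models:
        if mod.values.shape != (m, m):
            raise ValueError(f"model {mod.kind!r} shape does not match confusions")

    X = np.column_stack([mod.values.ravel() for mod in models])
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    design = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearModelError(
            "model set is collinear: " + ", ".join(mod.kind for mod in models)
        )

    p = np.clip(confusions, clip, 1 - clip)
    Y = np.log(p / (1 - p)).reshape(n_sub, -1)

    coef = None
    method = "two_stage"
    try:
        import statsmodels.api as sm

        endog = Y.ravel()
        exog = np.tile(design, (n_sub, 1))
        groups = np.repeat(np.arange(n_sub), Y.shape[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixed = sm.MixedLM(endog, exog, groups=groups, exog_re=exog)
            res = mixed.fit(reml=True, method="lbfgs", maxiter=200)
        if res.converged:
            method = "mixed"
            coef = {
                mod.kind: {
                    "b": float(res.params[i + 1]),
                    "se": float(res.bse[i + 1]),
                    "t": float(res.tvalues[i + 1]),
                }
                for i, mod in enumerate(models)
            }
    except Exception:
        coef = None

    if coef is None:
        betas = np.stack([np.linalg.lstsq(design, y, rcond=None)[0] for y in Y])
        coef = {}
        for i, mod in enumerate(models):
            b = betas[:, i + 1]
            se = b.std(ddof=1) / np.sqrt(n_sub)
            coef[mod.kind] = {
                "b": float(b.mean()),
                "se": float(se),
                "t": float(b.mean() / se) if se > 0 else 0.0,
            }
        method = "two_stage"
    return RSAFit(coefficients=coef, method=method, n_subjects=n_sub)


# ---------------------------------------------------------------------------
# Cross-classification generalization


def cross_classify(
    tf: TFPower,
    code_labels,
    gen_labels,
    config: DecodeConfig = DecodeConfig(),
    band: tuple[float, float] = (4.0, 7.0),
    period: tuple[float, float] = (-600.0, 0.0),
) -> dict:
    """Generalization of a code across instances of another variable.

    For each held-out instance g of the generalization variable: train class-
    averaged LDA rows on the other instances' trials; test (a) on class rows
    built from g's trials in the held-out fold (generalized score) and (b) on
    class rows built from an equal-sized subsample of training-instance trials
    in the held-out fold (reference score).  Rotating folds, instances, and
    iterations keeps both scores on identically sized training and test sets.
    """
    code_labels = np.asarray(code_labels)
    gen_labels = np.asarray(gen_labels)
    gens = np.unique(gen_labels)
    if gens.size < 2:
        raise ValueError("generalization variable needs >= 2 instances")
    classes = np.unique(code_labels)

    X = band_period_features(tf, band, period, config.window_samples)
    rng = np.random.default_rng(config.seed)
    joint = np.array([f"{c}|{g}" for c, g in zip(code_labels, gen_labels)])

    def class_rows(sel):
        rows = np.stack([X[sel & (code_labels == c)].mean(axis=0) for c in classes])
        return zscore_across(rows, axis=1)

    gen_acc, ref_acc, n_eval = 0.0, 0.0, 0
    y = np.arange(classes.size)
    for _ in range(config.n_iterations):
        fold = make_folds(joint, config.n_folds, rng)
        for g in gens:
            is_g = gen_labels == g
            for r in range(config.n_folds):
                # train on per-fold class rows from non-g instances
                rows_tr, ys = [], []
                for s in range(config.n_folds):
                    if s == r:
                        continue
                    rows_tr.append(class_rows((fold == s) & ~is_g))
                    ys.append(y)
                clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=config.shrinkage)
                clf.fit(np.concatenate(rows_tr), np.concatenate(ys))

                test_g = (fold == r) & is_g
                gen_acc += np.mean(clf.predict(class_rows(test_g)) == y)

                # size-matched reference: subsample non-g trials in fold r
                ref_sel = np.zeros_like(test_g)
                for c in classes:
                    pool = np.flatnonzero((fold == r) & ~is_g & (code_labels == c))
                    n_match = int(np.sum(test_g & (code_labels == c)))
                    take = rng.choice(pool, size=min(n_match, pool.size), replace=False)
                    ref_sel[take] = True
                ref_acc += np.mean(clf.predict(class_rows(ref_sel)) == y)
                n_eval += 1
    return {
        "generalized": gen_acc / n_eval,
        "reference": ref_acc / n_eval,
        "chance": 1.0 / classes.size,
    }


# ---------------------------------------------------------------------------
# Chaining asymmetry


@dataclass
class ChainingResult:
    mean_diff: float
    t: float
    p: float
    n_subjects: int
    subject_diffs: np.ndarray


def _within_chunk_transitions(schedule: pd.DataFrame):
    """Ordered (element_n, element_n+1) pairs for consecutive within-chunk
    steps, with the block index of each occurrence."""
    el = schedule["element"].to_numpy()
    wp = schedule["within_chunk_position"].to_numpy()
    blocks = schedule["block"].to_numpy()
    if "serial_index" in schedule:
        serial = schedule["serial_index"].to_numpy()
    else:
        serial = np.arange(len(schedule))
    trans = []
    for i in range(len(schedule) - 1):
        # consecutive trials of the same block that stay within a chunk
        if (wp[i + 1] == wp[i] + 1 and blocks[i + 1] == blocks[i]
                and serial[i + 1] == serial[i] + 1):
            trans.append((el[i], el[i + 1], blocks[i]))
    return trans


def chaining_asymmetry(
    tf: TFPower,
    schedule: pd.DataFrame,
    band: tuple[float, float] = (8.0, 12.0),
    period: tuple[float, float] = (-600.0, 0.0),
    window_samples: int = 25,
) -> float:
    """Per-subject chaining index: mean over within-chunk transitions A->B of
    z[cor(A_late, B_early)] - z[cor(A_early, B_late)].

    Element spatial patterns (electrode vectors of band/period-averaged
    power) are computed separately in the first (early) and second (late)
    half of blocks.  Transitions not observed in both halves are excluded
    with a warning.  Identical early and late data give exactly 0.
    """
    X = band_period_features(tf, band, period, window_samples)
    blocks = schedule["block"].to_numpy()
    cut = np.median(np.unique(blocks))
    early = blocks <= cut
    el = schedule["element"].to_numpy()

    def pattern(element, half_sel):
        sel = half_sel & (el == element)
        return X[sel].mean(axis=0) if sel.any() else None

    trans = _within_chunk_transitions(schedule)
    seen = {}
    for a, b, blk in trans:
        seen.setdefault((a, b), set()).add("early" if blk <= cut else "late")

    diffs = []
    for (a, b), halves in sorted(seen.items()):
        if halves != {"early", "late"}:
            warnings.warn(f"transition {a}->{b} absent in one half; excluded", stacklevel=2)
            continue
        a_e, a_l = pattern(a, early), pattern(a, ~early)
        b_e, b_l = pattern(b, early), pattern(b, ~early)
        if any(v is None for v in (a_e, a_l, b_e, b_l)):
            warnings.warn(f"element pattern missing for {a}->{b}; excluded", stacklevel=2)
            continue
        r_fwd = np.corrcoef(a_l, b_e)[0, 1]
        r_bwd = np.corrcoef(a_e, b_l)[0, 1]
        diffs.append(np.arctanh(np.clip(r_fwd, -1 + 1e-12, 1 - 1e-12))
                     - np.arctanh(np.clip(r_bwd, -1 + 1e-12, 1 - 1e-12)))
    if not diffs:
        raise ValueError("no within-chunk transition observed in both halves")
    return float(np.mean(diffs))


def chaining_test(subject_diffs) -> ChainingResult:
    """Group one-sample t-test of the per-subject chaining indices against 0."""
    d = np.asarray(subject_diffs, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need >= 2 subjects")
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        t, p = (0.0, 1.0)
    else:
        t = mean / (sd / np.sqrt(n))
        p = 2 * stats.t.sf(abs(t), n - 1)
    return ChainingResult(mean_diff=float(mean), t=float(t), p=float(p),
                          n_subjects=n, subject_diffs=d)
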