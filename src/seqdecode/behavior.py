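"""Behavioral analysis: exclusions, chunk-boundary contrasts, WM effects, and
single-trial brain-behavior models.

Repeated-measures contrasts are computed as subject-level condition means
followed by within-subject contrasts and group t-tests; for 1-df contrasts
the equivalent ANOVA F is t squared.  Within-subject confidence intervals use
subject-mean centering (Cousineau-Morey).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Default exclusion thresholds (ms).
RT_FLOOR_MS = 100.0
RETRIEVAL_CEIL_MS = 8000.0


def apply_exclusions(behavior: pd.DataFrame, variant: str = "exp1") -> pd.DataFrame:
    """Flag (never delete) trials excluded from analysis.

    Rules: error trials; the trial immediately following an error (within the
    same subject and block); RT < 100 ms; and, for the self-paced variant
    (exp2), retrieval time > 8000 ms.  Adds boolean ``excluded`` and a
    semicolon-joined ``exclusion_reason`` column.  Idempotent.
    """
    out = behavior.reset_index(drop=True).copy()
    n = len(out)
    reasons: list[list[str]] = [[] for _ in range(n)]

    err = ~out["correct"].to_numpy().astype(bool)
    for i in np.flatnonzero(err):
        reasons[i].append("error")

    same_ctx = np.ones(n, dtype=bool)
    for col in ("subject", "block"):
        if col in out:
            v = out[col].to_numpy()
            same_ctx[1:] &= v[1:] == v[:-1]
    post = np.zeros(n, dtype=bool)
    post[1:] = err[:-1] & same_ctx[1:]
    for i in np.flatnonzero(post):
        reasons[i].append("post_error")

    fast = out["rt"].to_numpy() < RT_FLOOR_MS
    for i in np.flatnonzero(fast):
        reasons[i].append("fast_rt")

    if variant == "exp2" and "retrieval_time" in out:
        slow = out["retrieval_time"].to_numpy() > RETRIEVAL_CEIL_MS
        for i in np.flatnonzero(slow):
            reasons[i].append("long_retrieval")

    out["excluded"] = [bool(r) for r in reasons]
    out["exclusion_reason"] = [";".join(r) for r in reasons]
    return out


@dataclass
class ContrastResult:
    contrast: str      # "pos1_vs_23", "pos2_vs_3", "boundary_x_wm"
    measure: str       # "rt", "accuracy", "retrieval_time"
    estimate: float
    se: float
    t: float
    F: float
    p: float
    df: int


def _subject_position_means(df: pd.DataFrame, measure: str) -> pd.DataFrame:
    if measure == "accuracy":
        vals = df.assign(v=df["correct"].astype(float))
    else:
        sel = ~df["excluded"] if "excluded" in df else np.ones(len(df), bool)
        vals = df[sel].assign(v=df.loc[sel, measure])
    return vals.pivot_table(index="subject", columns="within_chunk_position",
                            values="v", aggfunc="mean")


def _one_sample(d: np.ndarray, contrast: str, measure: str) -> ContrastResult:
    n = d.size
    est = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if est == 0 else np.inf
        p = 1.0 if est == 0 else 0.0
        se = 0.0
    else:
        se = sd / np.sqrt(n)
        t = est / se
        p = 2 * stats.t.sf(abs(t), n - 1)
    return ContrastResult(contrast=contrast, measure=measure, estimate=float(est),
                          se=float(se), t=float(t), F=float(t**2), p=float(p), df=n - 1)


def structure_contrasts(
    behavior: pd.DataFrame,
    wm_groups: dict | None = None,
    measures: tuple[str, ...] = ("rt", "accuracy"),
) -> list[ContrastResult]:
    """Chunk-structure contrasts on subject means.

    Two orthogonal within-chunk position contrasts per measure: position 1
    versus positions 2 and 3 (the chunk-boundary effect; for RT in ms, for
    accuracy as an error-rate difference expressed on the accuracy scale),
    and position 2 versus position 3.  With ``wm_groups`` (subject -> "high"/
    "low"), a boundary-by-WM-group interaction (independent-groups t on the
    boundary contrast) is added.  Subjects missing a position cell are
    dropped with a warning.
    """
    if behavior["subject"].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    results = []
    for measure in measures:
        means = _subject_position_means(behavior, measure)
        complete = means.dropna()
        if len(complete) < len(means):
            warnings.warn(
                f"{len(means) - len(complete)} subject(s) missing a cell for "
                f"{measure}; dropped", stacklevel=2,
            )
        if measure == "accuracy":
            # boundary effect = cost at position 1, reported as positive
            boundary = ((complete[2] + complete[3]) / 2 - complete[1]).to_numpy()
        else:
            boundary = (complete[1] - (complete[2] + complete[3]) / 2).to_numpy()
        results.append(_one_sample(boundary, "pos1_vs_23", measure))
        results.append(_one_sample((complete[2] - complete[3]).to_numpy(),
                                   "pos2_vs_3", measure))
        if wm_groups is not None:
            groups = np.array([wm_groups[s] for s in complete.index])
            lo, hi = boundary[groups == "low"], boundary[groups == "high"]
            if lo.size >= 2 and hi.size >= 2:
                t, p = stats.ttest_ind(lo, hi)
                est = lo.mean() - hi.mean()
                se = est / t if t != 0 else 0.0
                results.append(ContrastResult(
                    contrast="boundary_x_wm", measure=measure, estimate=float(est),
                    se=float(abs(se)), t=float(t), F=float(t**2), p=float(p),
                    df=lo.size + hi.size - 2,
                ))
    return results


def within_subject_ci(means: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Cousineau-Morey within-subject 95% CI half-widths per condition.

    ``means`` is subjects x conditions.  Subject means are removed, the grand
    mean restored, SDs corrected by sqrt(C/(C-1)).
    """
    C = means.shape[1]
    centered = means.sub(means.mean(axis=1), axis=0) + means.to_numpy().mean()
    sd = centered.std(ddof=1) * np.sqrt(C / (C - 1))
    n = len(means)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    return tcrit * sd / np.sqrt(n)


NUISANCE_CONTRASTS = ("trial_lin", "trial_quad", "block_lin", "block_quad",
                      "pos1_vs_23", "pos2_vs_3", "match")


def residualize_rt(behavior: pd.DataFrame) -> np.ndarray:
    """Residualize log RT per subject against nuisance structure.

    The nuisance design holds linear and quadratic trends of trial and block,
    the two within-chunk position contrasts, and match/mismatch.  Residuals
    are exactly orthogonal to every nuisance column (per-subject least
    squares); excluded trials get NaN.
    """
    out = np.full(len(behavior), np.nan)
    df = behavior.reset_index(drop=True)
    included = ~df["excluded"].to_numpy() if "excluded" in df else np.ones(len(df), bool)
    for s, sub in df[included].groupby("subject"):
        trial = np.arange(len(sub), dtype=float)
        trial = (trial - trial.mean()) / max(trial.std(), 1.0)
        block = sub["block"].to_numpy(dtype=float)
        block = (block - block.mean()) / max(block.std(), 1.0)
        pos = sub["within_chunk_position"].to_numpy()
        c1 = np.where(pos == 1, 2.0, -1.0)
        c2 = np.where(pos == 2, 1.0, np.where(pos == 3, -1.0, 0.0))
        match = sub["is_match"].to_numpy(dtype=float) if "is_match" in sub else np.zeros(len(sub))
        Xn = np.column_stack([np.ones(len(sub)), trial, trial**2, block, block**2,
                              c1, c2, match])
        if np.linalg.matrix_rank(Xn) < Xn.shape[1]:
            raise ValueError(f"nuisance design rank-deficient for subject {s}")
        y = np.log(sub["rt"].to_numpy())
        beta, *_ = np.linalg.lstsq(Xn, y, rcond=None)
        out[sub.index] = y - Xn @ beta
    return out


@dataclass
class MultilevelFit:
    coefficients: dict  # predictor -> {"b", "se", "t"}
    method: str         # "mixed" or "two_stage"
    n_subjects: int


def evidence_rt_model(
    residual_rt: np.ndarray,
    evidence: pd.DataFrame,
    predictors: tuple[str, ...] = ("alpha_element", "theta_position"),
) -> MultilevelFit:
    """Mixed model of residual log RT on single-trial decoder evidence.

    ``evidence`` carries a ``subject`` column and one column per predictor
    (logit posterior of the correct label, e.g. alpha-band element evidence
    and theta-band position evidence), entered simultaneously as fixed
    effects with per-subject random intercepts and slopes.  Falls back to the
    two-stage estimator (per-subject OLS, group t) on non-convergence.
    """
    df = evidence.reset_index(drop=True).copy()
    df["y"] = np.asarray(residual_rt, dtype=float)
    df = df.dropna(subset=["y", *predictors])
    if df["subject"].nunique() < 2:
        raise ValueError("need >= 2 subjects")

    X = df[list(predictors)].to_numpy()
    design = np.column_stack([np.ones(len(df)), X])
    coef = None
    method = "two_stage"
    try:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixed = sm.MixedLM(df["y"].to_numpy(), design,
                               groups=df["subject"].to_numpy(), exog_re=design)
            res = mixed.fit(reml=True, method="lbfgs", maxiter=200)
        if res.converged:
            method = "mixed"
            coef = {
                name: {"b": float(res.params[i + 1]), "se": float(res.bse[i + 1]),
                       "t": float(res.tvalues[i + 1])}
                for i, name in enumerate(predictors)
            }
    except Exception:
        coef = None

    if coef is None:
        betas = []
        for _, sub in df.groupby("subject"):
            Xs = np.column_stack([np.ones(len(sub)), sub[list(predictors)].to_numpy()])
            b, *_ = np.linalg.lstsq(Xs, sub["y"].to_numpy(), rcond=None)
            betas.append(b)
        betas = np.stack(betas)
        coef = {}
        for i, name in enumerate(predictors):
            b = betas[:, i + 1]
            se = b.std(ddof=1) / np.sqrt(b.size)
            coef[name] = {"b": float(b.mean()), "se": float(se),
                          "t": float(b.mean() / se) if se > 0 else 0.0}
        method = "two_stage"
    return MultilevelFit(coefficients=coef, method=method,
                         n_subjects=df["subject"].nunique())


def wm_decoding_comparison(summaries: pd.DataFrame, wm_groups: dict) -> dict:
    """WM-capacity group comparison of per-subject decoding summaries.

    ``summaries`` has columns subject, code, value (band/period-averaged
    accuracy).  Returns per-code independent-groups t-tests plus the code
    level (chunk_identity vs element) by WM-group interaction, computed as a
    two-sample t on the per-subject level difference.
    """
    out = {}
    df = summaries.copy()
    df["wm"] = df["subject"].map(wm_groups)
    for code, sub in df.groupby("code"):
        hi = sub.loc[sub["wm"] == "high", "value"].to_numpy()
        lo = sub.loc[sub["wm"] == "low", "value"].to_numpy()
        if hi.size < 2 or lo.size < 2:
            raise ValueError(f"WM group with < 2 subjects for code {code!r}")
        t, p = stats.ttest_ind(hi, lo)
        out[code] = {"diff": float(hi.mean() - lo.mean()), "t": float(t), "p": float(p)}

    wide = df.pivot_table(index="subject", columns="code", values="value")
    if {"chunk_identity", "element"} <= set(wide.columns):
        level_diff = (wide["chunk_identity"] - wide["element"]).dropna()
        g = np.array([wm_groups[s] for s in level_diff.index])
        hi, lo = level_diff[g == "high"], level_diff[g == "low"]
        if hi.size >= 2 and lo.size >= 2:
            t, p = stats.ttest_ind(hi, lo)
            out["level_x_wm"] = {"diff": float(hi.mean() - lo.mean()),
                                 "t": float(t), "p": float(p)}
    return out
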