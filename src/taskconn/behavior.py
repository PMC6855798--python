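"""Episodic-memory scoring, stimulation-effect tests, and the robust
brain-behavior regression.

Item recognition is the proportion of correct old/new decisions over all test
trials. Context recollection is conditional: the proportion of correct
context choices (one of six options) among items correctly recognised as old
with high confidence. The brain-behavior link regresses each subject's
context-recollection change (post-stim minus post-sham) on the subject's
connectivity interaction effect, (stim - sham, retrieval) - (stim - sham,
rest) on the Fisher-z scale, plus a tSNR nuisance covariate, using Huber
M-estimation with a Wald-type robust F for the connectivity term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "BehaviorScore",
    "score_memory",
    "behavior_contrast",
    "PairedTResult",
    "interaction_effect_per_subject",
    "robust_brain_behavior",
    "RobustFitResult",
]

N_CONTEXT_OPTIONS = 6


@dataclass(frozen=True)
class BehaviorScore:
    """Scores for one subject at one assessment."""

    item_recognition: float
    context_recollection: float  # NaN when no high-confidence hits
    n_high_conf_hits: int
    n_trials: int


def score_memory(trials: pd.DataFrame) -> BehaviorScore:
    """Score a trial table with columns is_old, resp_old, confidence,
    context_truth, context_choice.

    Context recollection is undefined (NaN, with a warning) when there are no
    high-confidence hits.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    choices = trials.loc[trials["is_old"], "context_choice"]
    if (choices < 1).any() or (choices > N_CONTEXT_OPTIONS).any():
        raise ValueError(f"context choices must be 1..{N_CONTEXT_OPTIONS}")
    correct_item = trials["resp_old"] == trials["is_old"]
    item = float(correct_item.mean())
    hc_hits = trials["is_old"] & trials["resp_old"] & (trials["confidence"] == "high")
    n_hc = int(hc_hits.sum())
    if n_hc == 0:
        warnings.warn("no high-confidence hits; context recollection undefined",
                      RuntimeWarning, stacklevel=2)
        context = float("nan")
    else:
        sub = trials.loc[hc_hits]
        context = float((sub["context_choice"] == sub["context_truth"]).mean())
    return BehaviorScore(item_recognition=item, context_recollection=context,
                         n_high_conf_hits=n_hc, n_trials=len(trials))


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_difference: float
    n_pairs: int
    one_tailed: bool


def behavior_contrast(scores: pd.DataFrame, measure: str = "context_recollection",
                      comparison: str = "post_stim_vs_post_sham",
                      one_tailed: bool = True) -> PairedTResult:
    """Paired t-test of a score between two assessments.

    ``scores`` is tidy with columns subject, assessment, and the measure.
    Subjects with an undefined score on either side are dropped pairwise
    (logged). One-tailed p is in the improvement (stim > sham) direction.
    """
    sides = {"post_stim_vs_post_sham": ("post_stim", "post_sham"),
             "pre_vs_pre": ("pre_stim", "pre_sham")}
    if comparison not in sides:
        raise ValueError(f"comparison must be one of {sorted(sides)}")
    a, b = sides[comparison]
    wide = scores.pivot(index="subject", columns="assessment", values=measure)
    pairs = wide[[a, b]].dropna()
    n_dropped = len(wide) - len(pairs)
    if n_dropped:
        warnings.warn(f"{n_dropped} subject(s) dropped pairwise (undefined "
                      f"{measure})", RuntimeWarning, stacklevel=2)
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    diff = (pairs[a] - pairs[b]).to_numpy(dtype=float)
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean)):
        if abs(mean) <= 1e-12:
            # no signal, no variance: conventional null result
            return PairedTResult(t=0.0, df=n - 1, p=0.5 if one_tailed else 1.0,
                                 mean_difference=0.0, n_pairs=n,
                                 one_tailed=one_tailed)
        raise ValueError("zero-variance nonzero differences: t undefined")
    t = mean / (sd / np.sqrt(n))
    if one_tailed:
        p = float(stats.t.sf(t, n - 1))
    else:
        p = float(2 * stats.t.sf(abs(t), n - 1))
    return PairedTResult(t=float(t), df=n - 1, p=p, mean_difference=mean,
                         n_pairs=n, one_tailed=one_tailed)


def interaction_effect_per_subject(values: pd.DataFrame,
                                   value_col: str = "value") -> pd.Series:
    """Per-subject interaction effect from 4 scans:
    (stim_retrieval - sham_retrieval) - (stim_rest - sham_rest).

    ``values`` needs columns subject, condition, task, and ``value_col``.
    """
    out = {}
    for subject, sub in values.groupby("subject"):
        cells = sub.set_index(["condition", "task"])[value_col]
        if cells.index.duplicated().any() or len(cells) != 4:
            raise ValueError(f"subject {subject}: need exactly one value per "
                             "condition x task cell")
        out[subject] = float(
            (cells[("stim", "retrieval")] - cells[("sham", "retrieval")])
            - (cells[("stim", "rest")] - cells[("sham", "rest")]))
    return pd.Series(out, name="interaction_effect")


@dataclass(frozen=True)
class RobustFitResult:
    slope: float
    intercept: float
    f_stat: float
    df: tuple[int, int]
    p: float
    r_squared: float
    n: int
    converged: bool


def robust_brain_behavior(effects, memory_change, tsnr=None,
                          max_iter: int = 200) -> RobustFitResult:
    """Huber M-estimation regression of memory change on the interaction effect.

    Fits ``memory_change ~ intercept + interaction_effect (+ tsnr)`` by
    iteratively reweighted least squares (Huber psi, tuning constant 1.345).
    The robust F is a Wald-type test of the connectivity coefficient on the
    robust covariance, with df (1, n - k); r_squared is the squared
    correlation between fitted and observed values.
    """
    x = np.asarray(effects, dtype=float)
    y = np.asarray(memory_change, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("effects and memory_change must be aligned 1D arrays")
    n = x.size
    if n < 5:
        raise ValueError("need >= 5 subjects")
    X = np.column_stack([np.ones(n), x])
    names = ["intercept", "effect"]
    if tsnr is not None:
        cov = np.asarray(tsnr, dtype=float)
        if cov.shape != x.shape:
            raise ValueError("tsnr covariate must align with subjects")
        if np.std(cov) < 1e-12:
            warnings.warn("constant tSNR covariate dropped (collinear with "
                          "intercept)", RuntimeWarning, stacklevel=2)
        else:
            X = np.column_stack([X, cov - cov.mean()])
            names.append("tsnr")
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345))
    fit = model.fit(maxiter=max_iter, tol=1e-8)
    converged = True
    if np.any(~np.isfinite(fit.params)):
        raise RuntimeError("robust fit did not converge")
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    k = X.shape[1]
    f_stat = (slope / se) ** 2
    df = (1, n - k)
    p = float(stats.f.sf(f_stat, *df))
    fitted = np.asarray(fit.fittedvalues)
    if np.std(fitted) < 1e-14 or np.std(y) < 1e-14:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    return RobustFitResult(slope=slope, intercept=float(fit.params[0]),
                           f_stat=float(f_stat), df=df, p=p, r_squared=r2,
                           n=n, converged=converged)
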