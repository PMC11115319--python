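"""Reliability and performance estimators.

Repeated test-set presentations let us split a neuron's response variance
into a stimulus-driven (explainable) part and observation noise:

    sigma2_noise   = E_j[ Var_t[ r_t | x_j ] ]      (within-image, unbiased)
    Var_exp[r]     = Var[r] - sigma2_noise          (over all single trials)
    EV             = Var_exp[r] / Var[r]

Neurons whose EV falls below a threshold (default 0.15, strict inequality:
exactly-threshold neurons are retained) are excluded from model evaluation —
their responses are too unreliable for any stimulus-driven model to predict.

Model performance is reported two ways:

* Pearson correlation between model predictions and the across-repeat mean
  response, averaged over neurons;
* FEVE — the fraction of explainable variance explained,
  FEVE = 1 - Var_res / Var_exp, where the residual variance is the mean
  squared single-trial residual minus the noise variance.  A perfect model
  of the stimulus-driven rate approaches FEVE = 1 no matter how noisy the
  neuron; FEVE is undefined when Var_exp <= 0.

The selectivity index SI = 1 - 2A measures sparseness from the curve of the
fraction of images whose response exceeds a threshold, over 100 evenly
spaced thresholds between the minimum and maximum response.  A uniform
response distribution gives A ~ 0.5 (SI ~ 0); a neuron responding to a
single image gives SI near 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


def _check_test_counts(test_counts: np.ndarray) -> np.ndarray:
    test_counts = np.asarray(test_counts, dtype=float)
    if test_counts.ndim != 3:
        raise ValueError("expected test counts of shape (images, repeats, neurons)")
    if test_counts.shape[1] < 2:
        raise ValueError("noise variance needs >= 2 repeats per image")
    return test_counts


def noise_variance(test_counts: np.ndarray) -> np.ndarray:
    """Observation-noise variance per neuron.

    Unbiased variance across repeats within each image, averaged over
    images.  ``test_counts``: (images, repeats, neurons).
    """
    test_counts = _check_test_counts(test_counts)
    return test_counts.var(axis=1, ddof=1).mean(axis=0)


def total_variance(test_counts: np.ndarray) -> np.ndarray:
    """Unbiased variance over all single-trial responses, per neuron."""
    test_counts = _check_test_counts(test_counts)
    flat = test_counts.reshape(-1, test_counts.shape[2])
    return flat.var(axis=0, ddof=1)


@dataclass
class NeuronReliability:
    total_var: np.ndarray
    noise_var: np.ndarray
    explainable_var: np.ndarray
    ev: np.ndarray


def reliability(test_counts: np.ndarray) -> NeuronReliability:
    """All reliability quantities in one pass over the test counts."""
    tv = total_variance(test_counts)
    nv = noise_variance(test_counts)
    ev_var = tv - nv
    with np.errstate(divide="ignore", invalid="ignore"):
        ev = np.where(tv > 0, ev_var / tv, np.nan)
    if np.any(tv <= 0):
        warnings.warn("neurons with zero total variance have undefined EV")
    return NeuronReliability(total_var=tv, noise_var=nv,
                             explainable_var=ev_var, ev=ev)


def explainable_variance_ratio(test_counts: np.ndarray) -> np.ndarray:
    """EV per neuron: (Var[r] - sigma2_noise) / Var[r]; NaN if Var[r] = 0."""
    return reliability(test_counts).ev


def filter_reliable(ev: np.ndarray, threshold: float = 0.15) -> np.ndarray:
    """Indices of neurons retained by the reliability filter.

    Neurons strictly below the threshold are removed; a neuron exactly at
    the threshold is retained.  NaN EVs are removed.
    """
    ev = np.asarray(ev, dtype=float)
    with np.errstate(invalid="ignore"):
        keep = ev >= threshold
    return np.flatnonzero(keep)


@dataclass
class ModelScore:
    correlation: np.ndarray      # per neuron
    feve: np.ndarray             # per neuron (NaN where undefined)
    residual_var: np.ndarray
    mean_correlation: float
    mean_feve: float


def feve(predictions: np.ndarray, test_counts: np.ndarray) -> np.ndarray:
    """Fraction of explainable variance explained, per neuron.

    ``predictions``: (images, neurons), aligned with the test images.  The
    residual variance averages squared *single-trial* residuals over repeats
    and images before subtracting the noise variance.  Neurons with
    Var_exp <= 0 get NaN (with a warning) — no model can be scored there.
    """
    test_counts = _check_test_counts(test_counts)
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != (test_counts.shape[0], test_counts.shape[2]):
        raise ValueError("predictions must be (n_test_images, n_neurons)")
    rel = reliability(test_counts)
    resid = test_counts - predictions[:, None, :]
    var_res = (resid ** 2).mean(axis=(0, 1)) - rel.noise_var
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(rel.explainable_var > 0,
                       1.0 - var_res / rel.explainable_var, np.nan)
    if np.any(rel.explainable_var <= 0):
        warnings.warn("FEVE undefined for neurons with nonpositive "
                      "explainable variance; reported as NaN")
    return out


def mean_test_correlation(predictions: np.ndarray, test_counts: np.ndarray) -> np.ndarray:
    """Pearson r between predictions and repeat-averaged responses, per neuron.

    NaN where either side has zero variance.  Requires >= 3 test images.
    """
    test_counts = _check_test_counts(test_counts)
    predictions = np.asarray(predictions, dtype=float)
    if test_counts.shape[0] < 3:
        raise ValueError("need at least 3 test images for a correlation")
    target = test_counts.mean(axis=1)           # (images, neurons)
    p = predictions - predictions.mean(axis=0)
    t = target - target.mean(axis=0)
    denom = np.sqrt((p ** 2).sum(axis=0) * (t ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, (p * t).sum(axis=0) / denom, np.nan)


def score_model(predictions: np.ndarray, test_counts: np.ndarray) -> ModelScore:
    """Correlation and FEVE for one model, with nan-aware population means."""
    test_counts = _check_test_counts(test_counts)
    rel = reliability(test_counts)
    corr = mean_test_correlation(predictions, test_counts)
    fv = feve(predictions, test_counts)
    resid = test_counts - predictions[:, None, :]
    var_res = (resid ** 2).mean(axis=(0, 1)) - rel.noise_var
    return ModelScore(
        correlation=corr, feve=fv, residual_var=var_res,
        mean_correlation=float(np.nanmean(corr)),
        mean_feve=float(np.nanmean(fv)) if np.any(np.isfinite(fv)) else float("nan"),
    )


@dataclass
class SparsenessResult:
    area: float                 # area under the fraction-above-threshold curve
    si: float                   # 1 - 2 * area
    thresholds: np.ndarray
    fraction_above: np.ndarray


def selectivity_index(mean_responses: np.ndarray,
                      n_thresholds: int = 100) -> SparsenessResult:
    """Sparseness of one neuron's mean responses across images.

    Thresholds are ``n_thresholds`` evenly spaced values from the minimum to
    the maximum response; the curve records the fraction of images whose
    response strictly exceeds each threshold, and A is its mean over
    thresholds (rectangle rule on the normalized threshold axis).
    Constant response vectors have no spread to measure: ValueError.
    """
    r = np.asarray(mean_responses, dtype=float).ravel()
    lo, hi = r.min(), r.max()
    if hi <= lo:
        raise ValueError("selectivity index undefined for constant responses")
    thresholds = np.linspace(lo, hi, n_thresholds)
    frac = (r[None, :] > thresholds[:, None]).mean(axis=1)
    area = float(frac.mean())
    return SparsenessResult(area=area, si=1.0 - 2.0 * area,
                            thresholds=thresholds, fraction_above=frac)


def population_selectivity(mean_responses: np.ndarray,
                           n_thresholds: int = 100) -> np.ndarray:
    """SI per neuron for an (images, neurons) response matrix; NaN where
    a neuron's responses are constant."""
    mean_responses = np.atleast_2d(np.asarray(mean_responses, dtype=float))
    out = np.full(mean_responses.shape[1], np.nan)
    for n in range(mean_responses.shape[1]):
        col = mean_responses[:, n]
        if col.max() > col.min():
            out[n] = selectivity_index(col, n_thresholds).si
    return out
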