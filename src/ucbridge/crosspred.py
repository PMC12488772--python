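"""Mean, progeny-variance and usefulness-criterion prediction of crosses.

For a prospective recipient x donor BC1S2 cross, the progeny mean is a
genome-proportion-weighted combination of the parental breeding values
(3/4 recipient + 1/4 donor, reflecting the backcross step); the progeny
variance is a quadratic form of marker effects in the progeny marker
covariance ``Sigma``, evaluated either with the posterior-mean effects
(VPM, "variance of posterior means") or averaged over MCMC samples
(PMV, "posterior mean variance").  The usefulness criterion combines
them, ``UC = mu + i h sigma2`` by default with selection intensity
``i = 2.07`` (5% selection) and accuracy ``h = 1``; putting the term on
the standard-deviation scale instead is exposed as an option and every
prediction records which scale it used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .brr import MarkerEffectPosterior
from .genetics import ProgenyCovariance, progeny_covariance_matrix

__all__ = [
    "CrossPrediction",
    "predict_cross_mean",
    "predict_cross_variance_vpm",
    "predict_cross_variance_pmv",
    "usefulness_criterion",
    "predict_cross",
    "SELECTION_INTENSITY_5PCT",
]

#: selection intensity at a 5% selected fraction
SELECTION_INTENSITY_5PCT = 2.07


@dataclass
class CrossPrediction:
    """Predicted mean, variance and UC of one donor x recipient cross."""

    recipient_id: str
    donor_id: str
    mu_hat: float
    sigma2_vpm: float
    sigma2_pmv: float
    uc_vpm: float
    uc_pmv: float
    selection_intensity: float = SELECTION_INTENSITY_5PCT
    accuracy: float = 1.0
    uc_scale: str = "variance"


def _check_parent(x, name):
    x = np.asarray(x, dtype=float)
    if not np.isin(x, (0.0, 2.0)).all():
        raise ValueError(f"{name} must be coded 0/2 (fully inbred)")
    return x


def predict_cross_mean(
    x_r: np.ndarray, x_d: np.ndarray, beta_hat: np.ndarray, intercept: float = 0.0
) -> float:
    """Backcross-weighted progeny mean ``3/4 x_R beta + 1/4 x_D beta``.

    The intercept, when the effects come from a model that carries one,
    is added once (not weighted by parent).
    """
    x_r = _check_parent(x_r, "recipient genotype")
    x_d = _check_parent(x_d, "donor genotype")
    beta_hat = np.asarray(beta_hat, dtype=float)
    return float(intercept + 0.75 * x_r @ beta_hat + 0.25 * x_d @ beta_hat)


def predict_cross_variance_vpm(beta_hat: np.ndarray, sigma) -> float:
    """Progeny variance from posterior-mean effects, ``beta' Sigma beta``.

    ``sigma`` may be a :class:`~ucbridge.genetics.ProgenyCovariance`
    (evaluated blockwise per chromosome) or a dense matrix.  The effect
    vector excludes the intercept.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    if isinstance(sigma, ProgenyCovariance):
        return sigma.quadratic_form(beta_hat)
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (beta_hat.shape[0], beta_hat.shape[0]):
        raise ValueError("Sigma dimension does not match effect vector")
    return float(beta_hat @ sigma @ beta_hat)


def predict_cross_variance_pmv(
    posterior: MarkerEffectPosterior | np.ndarray, sigma
) -> float:
    """Posterior-mean progeny variance, ``mean_s beta(s)' Sigma beta(s)``.

    ``posterior`` is either a fitted posterior (its intercept column is
    dropped) or a raw S x m sample matrix of effects.
    """
    if isinstance(posterior, MarkerEffectPosterior):
        betas = posterior.effects_samples
    else:
        betas = np.asarray(posterior, dtype=float)
    if betas.ndim != 2 or betas.shape[0] < 1:
        raise ValueError("posterior must contain at least one sample")
    if isinstance(sigma, ProgenyCovariance):
        return float(sigma.quadratic_form_samples(betas).mean())
    sigma = np.asarray(sigma, dtype=float)
    return float(np.einsum("si,ij,sj->s", betas, sigma, betas).mean())


def usefulness_criterion(
    mu: float,
    sigma2: float,
    intensity: float = SELECTION_INTENSITY_5PCT,
    accuracy: float = 1.0,
    scale: str = "variance",
) -> float:
    """Usefulness criterion of a cross.

    ``scale='variance'`` (default) computes ``mu + i h sigma2``; the
    classical standard-deviation form ``mu + i h sqrt(sigma2)`` is
    available as ``scale='sd'``.
    """
    if sigma2 < 0:
        raise ValueError("progeny variance must be nonnegative")
    if scale == "variance":
        spread = sigma2
    elif scale == "sd":
        spread = float(np.sqrt(sigma2))
    else:
        raise ValueError("uc scale must be 'variance' or 'sd'")
    return float(mu + intensity * accuracy * spread)


def predict_cross(
    recipient_id: str,
    donor_id: str,
    x_r: np.ndarray,
    x_d: np.ndarray,
    gmap,
    posterior: MarkerEffectPosterior,
    intensity: float = SELECTION_INTENSITY_5PCT,
    accuracy: float = 1.0,
    uc_scale: str = "variance",
) -> CrossPrediction:
    """End-to-end prediction of one cross from a fitted effect posterior.

    Assembles ``Sigma`` for the parent pair, then computes the
    backcross-weighted mean (posterior-mean intercept added once), both
    variance estimators and both UCs.
    """
    sigma = progeny_covariance_matrix(x_r, x_d, gmap)
    beta_hat = posterior.effects_mean
    mu = predict_cross_mean(x_r, x_d, beta_hat, intercept=posterior.intercept)
    v_vpm = predict_cross_variance_vpm(beta_hat, sigma)
    v_pmv = predict_cross_variance_pmv(posterior, sigma)
    return CrossPrediction(
        recipient_id=recipient_id,
        donor_id=donor_id,
        mu_hat=mu,
        sigma2_vpm=v_vpm,
        sigma2_pmv=v_pmv,
        uc_vpm=usefulness_criterion(mu, v_vpm, intensity, accuracy, uc_scale),
        uc_pmv=usefulness_criterion(mu, v_pmv, intensity, accuracy, uc_scale),
        selection_intensity=intensity,
        accuracy=accuracy,
        uc_scale=uc_scale,
    )
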