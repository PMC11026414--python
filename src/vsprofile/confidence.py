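"""Confidence gating of landscape predictions.

The kriging variances over a landscape grid are strongly bimodal: cells
near data points carry low variance, far-field cells approach the sill.  A
two-component Gaussian mixture fitted to the variances separates the two
regimes, and the mean of the low-variance component is the high-confidence
cutoff: cells with variance below it are kept.  Contour levels at the
cutoff and at successive standard deviations below it delineate the
high-confidence region on the landscape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .kriging import LandscapeGrid


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture over kriging variances.

    Components are ordered so that index 0 is the low-variance (high
    confidence) one; ``threshold`` equals its mean.  ``contour_levels``
    lists threshold - k * sd0 for k = 0, 1, ... while positive, on the
    variance scale; ``contour_levels_sd`` is the same level set expressed
    on the standard-deviation scale.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    threshold: float
    contour_levels: list[float] = field(default_factory=list)
    degenerate: bool = False
    log_likelihood: float = float("nan")

    @property
    def contour_levels_sd(self) -> list[float]:
        return [float(np.sqrt(l)) for l in self.contour_levels]


def fit_variance_mixture(variances, seed: int = 0,
                         n_restarts: int = 10) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture to grid variances.

    Values are sorted internally so the fit is invariant to input order;
    with a fixed seed the result is bitwise reproducible.  If the two
    component means are closer than 1e-3 of the overall spread the data is
    effectively unimodal and the threshold falls back to the overall mean.
    """
    v = np.asarray(variances, float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise ValueError("need at least 10 finite variances for the mixture")
    if np.any(v < 0):
        raise ValueError("variances must be nonnegative")
    if np.ptp(v) == 0:
        raise ValueError("zero spread in variances; mixture fit is degenerate")
    spread = float(np.std(v))
    v = np.sort(v)
    gm = GaussianMixture(n_components=2, n_init=n_restarts,
                         random_state=seed, covariance_type="full",
                         reg_covar=1e-12)
    gm.fit(v[:, None])
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    wts = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, wts = means[order], sds[order], wts[order]
    degenerate = abs(means[1] - means[0]) < 1e-3 * spread
    if degenerate:
        warnings.warn("variance mixture is effectively unimodal; using the "
                      "overall mean as the confidence threshold")
        threshold = float(np.mean(v))
    else:
        threshold = float(means[0])
    levels = []
    k = 0
    while True:
        level = threshold - k * float(sds[0])
        if level <= 0:
            break
        levels.append(level)
        k += 1
    return MixtureFit(means=means, sds=sds, weights=wts, threshold=threshold,
                      contour_levels=levels, degenerate=degenerate,
                      log_likelihood=float(gm.score(v[:, None]) * v.size))


def confidence_mask(fit: MixtureFit, grid: LandscapeGrid
                    ) -> tuple[np.ndarray, list[float]]:
    """Boolean mask of high-confidence cells (variance below the cutoff)
    plus the contour levels for plotting."""
    mask = grid.variance < fit.threshold
    return mask, list(fit.contour_levels)
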