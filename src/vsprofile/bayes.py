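"""Bayesian treatment of variogram-parameter uncertainty.

Ordinary kriging conditions on one best-fit variogram and ignores the
error in estimating it.  Here the (nugget, partial sill, range) parameters
of the selected family get a flat prior on a bounded grid around the
weighted-least-squares fit; each node is weighted by the Gaussian-process
marginal likelihood of the data under a constant-but-unknown mean (the
generalized-least-squares mean is profiled out with a flat prior on it).
Landscape predictions are then posterior-weighted averages of per-node
kriging surfaces, and the predictive variance adds the between-node spread
of the predictions to the average within-node kriging variance (law of
total variance) — so the Bayesian uncertainty is never smaller than the
average fixed-model uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.special import logsumexp

from .kriging import LandscapeGrid, default_y_grid
from .variogram import VariogramModel


@dataclass
class ParamPosterior:
    """Weighted variogram-parameter draws (c0, c, a) for one family."""

    family: str
    nodes: np.ndarray  # (k, 3) columns nugget, partial_sill, range
    log_like: np.ndarray
    weights: np.ndarray
    summary: dict = field(default_factory=dict)


def _log_marginal(xy: np.ndarray, z: np.ndarray,
                  model: VariogramModel) -> float:
    """GP log marginal likelihood with the constant mean integrated out
    under a flat prior."""
    n = z.size
    C = model.covariance(squareform(pdist(xy)))
    np.fill_diagonal(C, model.sill)
    C = C + 1e-10 * np.eye(n)
    try:
        cf = cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    Ci_z = cho_solve(cf, z)
    Ci_1 = cho_solve(cf, np.ones(n))
    s1 = float(np.ones(n) @ Ci_1)
    if s1 <= 0:
        return -np.inf
    m = float(np.ones(n) @ Ci_z) / s1
    r = z - m
    quad = float(r @ cho_solve(cf, r))
    return -0.5 * (logdet + np.log(s1) + quad + (n - 1) * np.log(2 * np.pi))


def default_grid_spec(fit: VariogramModel, n: int = 15) -> dict:
    """Bounded parameter box around a WLS fit, ``n`` nodes per axis."""
    sill = max(fit.sill, 1e-6)
    return {
        "nugget": (0.0, max(2.0 * fit.nugget, 0.1 * sill), n),
        "partial_sill": (max(0.25 * fit.partial_sill, 1e-3 * sill),
                         max(2.5 * fit.partial_sill, 0.2 * sill), n),
        "range": (max(0.25 * fit.range_, 1e-3),
                  3.0 * fit.range_, n),
    }


def variogram_posterior(x, y, z, family: str,
                        grid_spec: dict | None = None,
                        fit: VariogramModel | None = None,
                        prior=None) -> ParamPosterior:
    """Grid posterior over (nugget, partial sill, range) for one family.

    ``grid_spec`` maps each parameter to (lo, hi, count); by default it is
    built around ``fit`` (required in that case).  ``prior`` may be a
    callable (c0, c, a) -> unnormalized density; default flat.  Weights are
    normalized in log space; if every node underflows an error asks for a
    wider grid.
    """
    if grid_spec is None:
        if fit is None:
            raise ValueError("provide grid_spec or a fitted model to "
                             "anchor the default grid")
        grid_spec = default_grid_spec(fit)
    axes = []
    for key in ("nugget", "partial_sill", "range"):
        lo, hi, cnt = grid_spec[key]
        axes.append(np.linspace(lo, hi, int(cnt)))
    G0, G1, G2 = np.meshgrid(*axes, indexing="ij")
    nodes = np.column_stack([G0.ravel(), G1.ravel(), G2.ravel()])
    xy = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    zz = np.asarray(z, float)
    ll = np.empty(len(nodes))
    for k, (c0, c, a) in enumerate(nodes):
        if c0 + c <= 1e-9:
            ll[k] = -np.inf
            continue
        ll[k] = _log_marginal(xy, zz, VariogramModel(family, c0, c, a))
    lw = ll.copy()
    if prior is not None:
        with np.errstate(divide="ignore"):
            lw = lw + np.log([prior(*node) for node in nodes])
    if not np.any(np.isfinite(lw)):
        raise ValueError("all posterior weights underflow; widen the "
                         "parameter grid")
    lw = lw - logsumexp(lw[np.isfinite(lw)])
    w = np.where(np.isfinite(lw), np.exp(lw), 0.0)
    w = w / w.sum()
    mean = w @ nodes
    sd = np.sqrt(np.clip(w @ nodes**2 - mean**2, 0.0, None))
    summary = {p: {"mean": float(mean[i]), "sd": float(sd[i])}
               for i, p in enumerate(("nugget", "partial_sill", "range"))}
    return ParamPosterior(family=family, nodes=nodes, log_like=ll,
                          weights=w, summary=summary)


def bayes_krige_grid(posterior: ParamPosterior, x, y, z, chain_length: int,
                     y_grid=None, max_nodes: int = 400,
                     mass: float = 1.0 - 1e-8) -> LandscapeGrid:
    """Posterior-averaged landscape.

    Nodes are taken in decreasing weight until ``mass`` of the posterior is
    covered (capped at ``max_nodes``) and renormalized; each contributes an
    ordinary-kriging surface.  The returned prediction is the weighted mean
    and the variance the weighted within-node variance plus the weighted
    between-node prediction variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    n = z.size
    if y_grid is None:
        y_grid = default_y_grid(y)
    y_grid = np.asarray(y_grid, float)
    x_grid = np.arange(1, chain_length + 1) / chain_length
    X, Y = np.meshgrid(x_grid, y_grid)
    targets = np.column_stack([X.ravel(), Y.ravel()])
    xy = np.column_stack([x, y])
    Ddata = squareform(pdist(xy))
    Dtarg = cdist(xy, targets)

    order = np.argsort(posterior.weights)[::-1]
    cum = np.cumsum(posterior.weights[order])
    k = int(np.searchsorted(cum, mass) + 1)
    keep = order[:min(k, max_nodes)]
    w = posterior.weights[keep]
    w = w / w.sum()

    zsum = np.zeros(targets.shape[0])
    z2sum = np.zeros(targets.shape[0])
    vsum = np.zeros(targets.shape[0])
    ones = np.ones((1, targets.shape[0]))
    for wk, (c0, c, a) in zip(w, posterior.nodes[keep]):
        model = VariogramModel(posterior.family, c0, c, a)
        A = np.empty((n + 1, n + 1))
        A[:n, :n] = model.covariance(Ddata)
        A[np.arange(n), np.arange(n)] = model.sill
        A[:n, n] = 1.0
        A[n, :n] = 1.0
        A[n, n] = 0.0
        B = np.vstack([model.covariance(Dtarg), ones])
        W = np.linalg.solve(A, B)
        zk = W[:-1].T @ z
        vk = np.clip(model.sill - (np.sum(W[:-1] * B[:-1], axis=0) + W[-1]),
                     0.0, None)
        zsum += wk * zk
        z2sum += wk * zk**2
        vsum += wk * vk
    zbar = zsum
    between = np.clip(z2sum - zbar**2, 0.0, None)
    var = vsum + between
    md = {"family": posterior.family, "bayesian": True,
          "n_nodes_used": int(keep.size), "chain_length": chain_length,
          "within_variance": vsum.reshape(X.shape)}
    return LandscapeGrid(x_grid=x_grid, y_grid=y_grid,
                         z_pred=zbar.reshape(X.shape),
                         variance=var.reshape(X.shape), metadata=md)
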