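"""Molecular variogram: pairwise semivariance cloud, binning, and parametric fits.

The variogram describes how the dissimilarity of a phenotype value z grows
with the separation of two variants in the (normalized residue position,
phenotype) plane.  For a pair of observations separated by a Euclidean
distance h, the semivariance is gamma = (z_i - z_j)^2 / 2.  Binned averages
of the pair cloud are fitted with one of the standard isotropic families
(spherical, exponential, gaussian, pure nugget) by weighted least squares,
and the winning family is chosen by leave-one-out cross-validation of the
resulting kriging predictor.

The fitted model defines both the semivariogram gamma(h) and the spatial
covariance C(h) = C(0) - gamma(h), where the sill C(0) = nugget + partial
sill is the global variance plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.spatial.distance import pdist

FAMILIES = ("spherical", "exponential", "gaussian", "pure_nugget")


@dataclass(frozen=True)
class VariogramModel:
    """Parametric semivariogram gamma(h) and induced covariance C(h).

    Parameters
    ----------
    family : str
        One of ``spherical``, ``exponential``, ``gaussian``, ``pure_nugget``.
    nugget : float
        c0 >= 0, the discontinuity of gamma at h -> 0+ (micro-scale variance
        plus measurement error).
    partial_sill : float
        c >= 0, the spatially structured variance component.
    range_ : float
        a > 0, the distance parameter of the family.  Ignored (may be nan)
        for ``pure_nugget``.
    diagnostics : dict
        Free-form fit metadata (RSS, LOOCV r, ...).  Not part of equality.
    """

    family: str
    nugget: float
    partial_sill: float
    range_: float = float("nan")
    diagnostics: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be nonnegative")
        if self.family != "pure_nugget" and not self.range_ > 0:
            raise ValueError("range must be positive")

    @property
    def sill(self) -> float:
        """C(0) = nugget + partial sill, the variogram plateau."""
        return self.nugget + self.partial_sill

    def _structure(self, h: np.ndarray) -> np.ndarray:
        """Normalized structural component g(h) in [0, 1] (0 at h=0)."""
        if self.family == "pure_nugget":
            return np.zeros_like(h)
        t = h / self.range_
        if self.family == "spherical":
            return np.where(t < 1.0, 1.5 * t - 0.5 * t**3, 1.0)
        if self.family == "exponential":
            return 1.0 - np.exp(-t)
        return 1.0 - np.exp(-(t**2))  # gaussian

    def gamma(self, h) -> np.ndarray:
        """Semivariance gamma(h); gamma(0) = 0 by convention."""
        h = np.asarray(h, dtype=float)
        g = self.nugget + self.partial_sill * self._structure(h)
        return np.where(h > 0, g, 0.0)

    def covariance(self, h) -> np.ndarray:
        """Spatial covariance C(h) = C(0) - gamma(h)."""
        return self.sill - self.gamma(h)

    @property
    def effective_range(self) -> float:
        """Smallest distance at which gamma reaches 95% of the sill.

        Puts the three families' distance parameters on a common footing
        (for the exponential, about 3x the range parameter).  Zero for a
        pure-nugget model and for near-nugget fits whose structured part
        never lifts gamma past 95% of the plateau.
        """
        if self.family == "pure_nugget" or self.partial_sill == 0:
            return 0.0
        q = (0.95 * self.sill - self.nugget) / self.partial_sill
        if q <= 0:
            return 0.0
        if self.family == "exponential":
            return -self.range_ * float(np.log1p(-q))
        if self.family == "gaussian":
            return self.range_ * float(np.sqrt(-np.log1p(-q)))
        # spherical: solve 1.5 t - 0.5 t^3 = q on [0, 1]
        if q >= 1.0:
            return self.range_
        t = brentq(lambda t: 1.5 * t - 0.5 * t**3 - q, 0.0, 1.0)
        return self.range_ * float(t)


def range_in_residues(range_norm: float, chain_length: int) -> int:
    """Convert a correlation range on the normalized [0, 1] position axis
    to a residue count on a chain of ``chain_length`` residues."""
    return int(round(range_norm * chain_length))


@dataclass
class VariogramCloud:
    """All unordered pairs (i, j) with their distance h and semivariance."""

    i: np.ndarray
    j: np.ndarray
    h: np.ndarray
    gamma: np.ndarray

    def __len__(self) -> int:
        return self.h.size


@dataclass
class EmpiricalVariogram:
    """Binned variogram: per-lag mean semivariance with its SEM."""

    lag_center: np.ndarray
    mean_gamma: np.ndarray
    sem_gamma: np.ndarray
    n_pairs: np.ndarray
    max_lag: float
    bin_width: float = float("nan")

    def __len__(self) -> int:
        return self.lag_center.size


def variogram_cloud(x, y, z) -> VariogramCloud:
    """Distance/semivariance for every unordered pair of points.

    h follows the Euclidean metric on the (x, y) plane and
    gamma = (z_i - z_j)^2 / 2.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if x.size < 3:
        raise ValueError("variogram cloud needs at least 3 points")
    for name, arr in (("x", x), ("y", y), ("z", z)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise ValueError(f"non-finite {name} at indices {bad.tolist()}")
    xy = np.column_stack([x, y])
    h = pdist(xy)
    g = pdist(z[:, None], metric="sqeuclidean") / 2.0
    i, j = np.triu_indices(x.size, k=1)
    return VariogramCloud(i=i, j=j, h=h, gamma=g)


def bin_cloud(cloud: VariogramCloud, n_bins: int = 12,
              max_lag: float | None = None) -> EmpiricalVariogram:
    """Average the pair cloud over equal-width distance intervals.

    Pairs beyond ``max_lag`` (default: half the maximum pair distance)
    are dropped; empty bins are omitted.  SEM within a single-pair bin
    is reported as 0.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    if max_lag is None:
        max_lag = float(cloud.h.max()) / 2.0
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    keep = cloud.h <= max_lag
    h, g = cloud.h[keep], cloud.gamma[keep]
    idx = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
    centers, means, sems, counts = [], [], [], []
    for b in range(n_bins):
        gb = g[idx == b]
        if gb.size == 0:
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        means.append(gb.mean())
        sems.append(gb.std(ddof=1) / np.sqrt(gb.size) if gb.size > 1 else 0.0)
        counts.append(gb.size)
    return EmpiricalVariogram(
        lag_center=np.array(centers), mean_gamma=np.array(means),
        sem_gamma=np.array(sems), n_pairs=np.array(counts, dtype=int),
        max_lag=float(max_lag), bin_width=float(max_lag) / n_bins)


def _wls_fit_family(emp: EmpiricalVariogram, family: str) -> VariogramModel | None:
    """Weighted least squares on bin means, weights = pair counts."""
    hb, gb, w = emp.lag_center, emp.mean_gamma, emp.n_pairs.astype(float)
    sw = np.sqrt(w)
    gmax = max(float(gb.max()), 1e-12)
    if family == "pure_nugget":
        c0 = float(np.average(gb, weights=w))
        rss = float(np.sum(w * (gb - c0) ** 2))
        return VariogramModel("pure_nugget", c0, 0.0,
                              diagnostics={"rss": rss})
    a_hi = 2.0 * emp.max_lag

    def resid(theta):
        c0, c, a = theta
        m = VariogramModel(family, c0, c, a)
        return sw * (m.gamma(hb) - gb)

    best = None
    for a0 in (emp.max_lag / 4, emp.max_lag / 2, emp.max_lag):
        c0_0 = min(max(float(gb[0]), 0.0), gmax)
        x0 = [c0_0, max(gmax - c0_0, 1e-6), a0]
        try:
            sol = least_squares(resid, x0, bounds=([0, 0, 1e-9],
                                                   [5 * gmax, 5 * gmax, a_hi]))
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        return None
    rss, (c0, c, a) = best
    return VariogramModel(family, float(c0), float(c), float(a),
                          diagnostics={"rss": rss})


def fit_variogram(emp: EmpiricalVariogram,
                  families: tuple[str, ...] = FAMILIES,
                  data: tuple | None = None) -> VariogramModel:
    """Fit candidate families and select one.

    Each family is fitted to the binned empirical variogram by weighted
    least squares (weights = pairs per bin, bounds c0 >= 0, c >= 0,
    0 < a <= 2 * max_lag).  When ``data`` — a ``(x, y, z)`` triple of the
    underlying points — is supplied, the winner is the family whose kriging
    predictor achieves the highest leave-one-out Pearson r, ties broken by
    lower RSS; otherwise lowest RSS wins.  If every optimizer fails a
    pure-nugget model is returned with a warning.
    """
    if len(emp) < 3:
        raise ValueError("need at least 3 occupied bins to fit a variogram")
    fits: list[VariogramModel] = []
    for fam in families:
        m = _wls_fit_family(emp, fam)
        if m is not None:
            fits.append(m)
    if not fits:
        warnings.warn("all variogram fits failed; falling back to pure nugget")
        c0 = float(np.average(emp.mean_gamma, weights=emp.n_pairs))
        return VariogramModel("pure_nugget", c0, 0.0,
                              diagnostics={"fallback": True})
    if data is not None:
        from .kriging import loocv  # deferred: kriging imports this module

        x, y, z = data
        scored = []
        for m in fits:
            try:
                res = loocv(x, y, z, m)
                r = res.pearson_r if np.isfinite(res.pearson_r) else -np.inf
                m = replace(m, diagnostics={**m.diagnostics,
                                            "loocv_r": res.pearson_r,
                                            "loocv_p": res.p_value})
            except Exception:
                r = -np.inf
            scored.append((r, -m.diagnostics["rss"], m))
        scored.sort(key=lambda t: (t[0], t[1]), reverse=True)
        winner = scored[0][2]
        # adopt spatial structure only on evidence: the winning kriging
        # model must cross-validate with significantly positive r,
        # otherwise the data shows no usable spatial covariance
        r = winner.diagnostics.get("loocv_r", float("nan"))
        p = winner.diagnostics.get("loocv_p", float("nan"))
        if (winner.family != "pure_nugget"
                and not (np.isfinite(r) and r > 0 and p / 2 < 0.05)):
            c0 = float(np.average(emp.mean_gamma, weights=emp.n_pairs))
            winner = VariogramModel(
                "pure_nugget", c0, 0.0,
                diagnostics={**winner.diagnostics,
                             "no_spatial_evidence": True})
    else:
        winner = min(fits, key=lambda m: m.diagnostics["rss"])
    # a structure below the lag resolution is indistinguishable from nugget
    if (winner.family != "pure_nugget" and np.isfinite(emp.bin_width)
            and winner.effective_range < emp.bin_width):
        winner = VariogramModel(
            "pure_nugget", winner.sill, 0.0,
            diagnostics={**winner.diagnostics,
                         "collapsed_from": winner.family})
    return winner
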