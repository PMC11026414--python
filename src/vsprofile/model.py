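"""Model/Results front end for variation spatial profiling.

:class:`PhenotypeLandscape` is the model object: variant points scattered
in the (normalized residue position, phenotype y) plane carrying a second
phenotype z.  ``fit()`` runs the full inference chain — empirical
variogram, weighted-least-squares family fit with leave-one-out model
selection, ordinary-kriging landscape with per-cell variance, two-component
mixture confidence gate, and the inverse-variance-weighted residue barcode
— and returns a :class:`LandscapeResults` holding every intermediate
object, with ``summary()`` for a human-readable account and ``predict()``
for new locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import barcode as _barcode
from . import bayes as _bayes
from . import confidence as _confidence
from . import kriging as _kriging
from . import variogram as _variogram
from .data import VariantDataset, select_spatial


def _gate(grid, mixture_seed: int, n_restarts: int):
    """Confidence gate for a landscape; a constant-variance surface (pure
    nugget model) has no low/high regime, so every cell passes."""
    if np.ptp(grid.variance) == 0:
        warnings.warn("constant kriging variance: confidence gate is "
                      "vacuous, all cells pass")
        return None, np.ones_like(grid.variance, dtype=bool)
    mixture = _confidence.fit_variance_mixture(
        grid.variance, seed=mixture_seed, n_restarts=n_restarts)
    mask, _ = _confidence.confidence_mask(mixture, grid)
    return mixture, mask


class PhenotypeLandscape:
    """Kriging landscape model for one (phenotype_y -> phenotype_z) pair.

    Parameters
    ----------
    x, y, z : array-like
        Normalized residue positions (position / chain_length), phenotype
        y values, and phenotype z values of the variant panel.
    chain_length : int
        Number of residues in the full-length chain.
    names : dict, optional
        Labels for reporting, e.g. ``{"y": "monomer", "z": "activity",
        "condition": "vehicle"}``.
    """

    def __init__(self, x, y, z, chain_length: int,
                 names: dict | None = None) -> None:
        self.x = np.asarray(x, float).ravel()
        self.y = np.asarray(y, float).ravel()
        self.z = np.asarray(z, float).ravel()
        if not (self.x.size == self.y.size == self.z.size):
            raise ValueError("x, y, z must have equal length")
        self.chain_length = int(chain_length)
        self.names = names or {}

    @classmethod
    def from_dataset(cls, dataset: VariantDataset, phenotype_y: str,
                     phenotype_z: str, condition: str) -> "PhenotypeLandscape":
        pts = select_spatial(dataset, phenotype_y, phenotype_z, condition)
        return cls(pts["x"], pts["y"], pts["z"], dataset.chain_length,
                   names={"y": phenotype_y, "z": phenotype_z,
                          "condition": condition})

    @property
    def nobs(self) -> int:
        return self.z.size

    def fit(self, families: tuple[str, ...] = _variogram.FAMILIES,
            n_bins: int = 12, max_lag: float | None = None,
            y_grid=None, mixture_seed: int = 0, n_restarts: int = 10,
            ivw_fallback: str = "na", bayesian: bool = False,
            bayes_grid_nodes: int = 15) -> "LandscapeResults":
        """Run the full landscape inference chain.

        With ``bayesian=True`` a posterior over the selected family's
        variogram parameters is also computed and a posterior-averaged
        landscape (with its own mask and barcode) attached to the results.
        """
        cloud = _variogram.variogram_cloud(self.x, self.y, self.z)
        emp = _variogram.bin_cloud(cloud, n_bins=n_bins, max_lag=max_lag)
        model = _variogram.fit_variogram(emp, families,
                                         data=(self.x, self.y, self.z))
        cv = _kriging.loocv(self.x, self.y, self.z, model)
        grid = _kriging.krige_grid(self.x, self.y, self.z, model,
                                   self.chain_length, y_grid=y_grid,
                                   metadata=dict(self.names))
        mixture, mask = _gate(grid, mixture_seed, n_restarts)
        code = _barcode.ivw_barcode(grid, mask, fallback=ivw_fallback)
        res = LandscapeResults(model=self, variogram=model, empirical=emp,
                               cloud=cloud, loocv=cv, grid=grid,
                               mixture=mixture, mask=mask, barcode=code)
        if bayesian:
            spec = _bayes.default_grid_spec(model, n=bayes_grid_nodes)
            post = _bayes.variogram_posterior(self.x, self.y, self.z,
                                              model.family, grid_spec=spec)
            bgrid = _bayes.bayes_krige_grid(post, self.x, self.y, self.z,
                                            self.chain_length,
                                            y_grid=grid.y_grid)
            bmix, bmask = _gate(bgrid, mixture_seed, n_restarts)
            res.posterior = post
            res.bayes_grid = bgrid
            res.bayes_mixture = bmix
            res.bayes_mask = bmask
            res.bayes_barcode = _barcode.ivw_barcode(bgrid, bmask,
                                                     fallback=ivw_fallback)
        return res


@dataclass
class LandscapeResults:
    """Everything the landscape fit produced."""

    model: PhenotypeLandscape
    variogram: _variogram.VariogramModel
    empirical: _variogram.EmpiricalVariogram
    cloud: _variogram.VariogramCloud
    loocv: _kriging.LOOCVResult
    grid: _kriging.LandscapeGrid
    mixture: _confidence.MixtureFit
    mask: np.ndarray
    barcode: _barcode.ResidueBarcode
    posterior: object = field(default=None)
    bayes_grid: object = field(default=None)
    bayes_mixture: object = field(default=None)
    bayes_mask: object = field(default=None)
    bayes_barcode: object = field(default=None)

    def predict(self, x, y):
        """Kriged prediction and variance at arbitrary locations."""
        system = _kriging.build_system(self.model.x, self.model.y,
                                       self.model.z, self.variogram)
        zstar, var, _ = _kriging._solve_targets(
            system, np.atleast_1d(x), np.atleast_1d(y))
        return zstar, var

    @property
    def mask_fraction(self) -> float:
        return float(self.mask.mean())

    def summary(self) -> str:
        m = self.variogram
        names = self.model.names
        L = self.model.chain_length
        eff = m.effective_range
        lines = [
            "Phenotype landscape (ordinary kriging)",
            "=" * 54,
            f"landscape: {names.get('y', 'y')} -> {names.get('z', 'z')}"
            f"   condition: {names.get('condition', '-')}",
            f"n points:  {self.model.nobs:<6d} chain length: {L}",
            "-" * 54,
            f"variogram family:   {m.family}",
            f"nugget (c0):        {m.nugget:.4f}",
            f"partial sill (c):   {m.partial_sill:.4f}",
            f"sill C(0):          {m.sill:.4f}",
            f"range (a):          {m.range_:.4f}",
            f"effective range:    {eff:.4f}"
            f"  (~{_variogram.range_in_residues(eff, L)} residues)",
            f"fit RSS:            {m.diagnostics.get('rss', float('nan')):.4g}",
            f"LOOCV Pearson r:    {self.loocv.pearson_r:.3f}"
            f"  (p = {self.loocv.p_value:.2e})",
            "-" * 54,
        ]
        if self.mixture is not None:
            lines += [
                f"variance mixture:   means {self.mixture.means[0]:.4f} / "
                f"{self.mixture.means[1]:.4f}",
                f"confidence cutoff:  {self.mixture.threshold:.4f}",
            ]
        else:
            lines.append("variance mixture:   skipped (constant variance)")
        lines += [
            f"high-confidence:    {100 * self.mask_fraction:.1f}% of cells",
            f"barcode coverage:   "
            f"{int(np.isfinite(self.barcode.values).sum())}/{L} residues",
        ]
        if self.bayes_grid is not None:
            r = np.corrcoef(self.grid.z_pred.ravel(),
                            self.bayes_grid.z_pred.ravel())[0, 1]
            lines.append("-" * 54)
            lines.append(f"Bayesian agreement: r = {r:.3f} "
                         f"({self.bayes_grid.metadata['n_nodes_used']} "
                         "posterior nodes)")
        return "\n".join(lines)
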