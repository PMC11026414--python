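"""Synthetic variant panels with the generative structure kriging assumes.

Each simulated phenotype value decomposes as

    z(x, y) = mu + W(x, y) + eps

with a constant local mean mu, a zero-mean spatially correlated field W
whose covariance is C(h) = C(0) - gamma(h) for a chosen variogram (the
nugget enters as an independent per-point component, so the marginal
variance of W is the full sill), and iid replicate noise eps.  The default
panel emulates a study of 76 variants scattered over a 418-residue chain
with triplicate measurements on WT-normalized scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data import VariantDataset, _col, replicates_to_str
from .variogram import VariogramModel

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth for one simulated condition.

    ``replicate_sd`` is measurement noise per replicate on the normalized
    phenotype scale; 0.05 emulates tight triplicate assays.  ``mean_level``
    defaults to 0.73, a realistic panel-wide mean for a WT-normalized
    activity phenotype dominated by partially defective variants.
    """

    n_variants: int = 76
    chain_length: int = 418
    variogram: VariogramModel = field(
        default_factory=lambda: VariogramModel("exponential", 0.05, 1.0, 0.3))
    replicate_sd: float = 0.05
    n_replicates: int = 3
    mean_level: float = 0.73
    y_mode: str = "independent"  # independent | latent
    seed: int = 0
    phenotype_y: str = "monomer"
    phenotype_z: str = "activity"
    condition: str = "vehicle"

    def __post_init__(self) -> None:
        if self.n_variants < 3:
            raise ValueError("need at least 3 variants")
        if self.chain_length < 1:
            raise ValueError("chain_length must be positive")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.y_mode not in ("independent", "latent"):
            raise ValueError("y_mode must be 'independent' or 'latent'")


@dataclass(frozen=True)
class ConditionEffect:
    """How the treated condition's ground truth differs from basal."""

    range_factor: float = 1.0
    sill_factor: float = 1.0
    mean_shift: float = 0.0
    shared_seed: bool = True

    def __post_init__(self) -> None:
        if self.range_factor <= 0 or self.sill_factor <= 0:
            raise ValueError("range and sill factors must be positive")


def _latent_field(xy: np.ndarray, model: VariogramModel,
                  normals: np.ndarray) -> np.ndarray:
    """One zero-mean draw with covariance C(h) = C(0) - gamma(h)."""
    if model.sill == 0:
        return np.zeros(len(xy))
    C = model.covariance(squareform(pdist(xy)))
    np.fill_diagonal(C, model.sill)
    C = C + 1e-10 * np.eye(len(xy))
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as e:
        raise ValueError(
            f"covariance matrix not positive definite after jitter for "
            f"family={model.family} nugget={model.nugget} "
            f"partial_sill={model.partial_sill} range={model.range_}") from e
    return L @ normals


def _draws(config: SyntheticConfig, rng: np.random.Generator) -> dict:
    """All randomness for one dataset, drawn up front so that two
    conditions can share it."""
    n = config.n_variants
    L = config.chain_length
    if n <= L:
        positions = np.sort(rng.choice(np.arange(1, L + 1), size=n,
                                       replace=False))
    else:
        positions = np.sort(rng.integers(1, L + 1, size=n))
    return {
        "positions": positions,
        "alt_idx": rng.integers(0, len(_AA), size=(n, 2)),
        "y_uniform": rng.uniform(0.0, 1.0, size=n),
        "y_normals": rng.standard_normal(n),
        "z_normals": rng.standard_normal(n),
        "noise": rng.standard_normal((n, config.n_replicates)),
    }


def _assemble(config: SyntheticConfig, draws: dict) -> VariantDataset:
    n = config.n_variants
    positions = draws["positions"]
    x = positions / config.chain_length
    if config.y_mode == "independent":
        y = draws["y_uniform"].copy()
    else:
        # second latent field over the position axis, squashed to [0, 1]
        xy0 = np.column_stack([x, np.zeros(n)])
        w = _latent_field(xy0, config.variogram, draws["y_normals"])
        lo, hi = w.min(), w.max()
        y = (w - lo) / (hi - lo) if hi > lo else np.full(n, 0.5)
    # re-jitter exact (x, y) duplicates so the kriging matrix stays regular
    xy = np.column_stack([x, y])
    seen: dict[tuple, int] = {}
    for k in range(n):
        key = (xy[k, 0], xy[k, 1])
        while key in seen:
            xy[k, 1] += 1e-6
            key = (xy[k, 0], xy[k, 1])
        seen[key] = k
    y = xy[:, 1]

    latent = config.mean_level + _latent_field(xy, config.variogram,
                                               draws["z_normals"])
    reps = latent[:, None] + config.replicate_sd * draws["noise"]
    z_mean = reps.mean(axis=1)
    if config.n_replicates > 1 and config.replicate_sd > 0:
        z_sd = reps.std(axis=1, ddof=1)
    else:
        z_sd = np.zeros(n)
        if config.replicate_sd == 0:
            z_mean = latent.copy()  # exact: no-noise replicates are latent

    labels = []
    used = set()
    for k in range(n):
        ref = _AA[draws["alt_idx"][k, 0]]
        alt = _AA[draws["alt_idx"][k, 1]]
        if alt == ref:
            alt = _AA[(draws["alt_idx"][k, 1] + 1) % len(_AA)]
        lab = f"{ref}{positions[k]}{alt}"
        while lab in used:
            alt = _AA[(_AA.index(alt) + 1) % len(_AA)]
            if alt == ref:
                alt = _AA[(_AA.index(alt) + 1) % len(_AA)]
            lab = f"{ref}{positions[k]}{alt}"
        used.add(lab)
        labels.append(lab)

    cond = config.condition
    df = pd.DataFrame({
        "variant": labels,
        "position": pd.array(positions, dtype="Int64"),
        "x": x,
        _col(config.phenotype_y, cond, "mean"): y,
        _col(config.phenotype_y, cond, "sd"): np.zeros(n),
        _col(config.phenotype_y, cond, "n"): np.full(n, 1, dtype=int),
        _col(config.phenotype_z, cond, "mean"): z_mean,
        _col(config.phenotype_z, cond, "sd"): z_sd,
        _col(config.phenotype_z, cond, "n"):
            np.full(n, config.n_replicates, dtype=int),
        _col(config.phenotype_z, cond, "replicates"):
            [replicates_to_str(r) for r in reps],
    })
    meta = {"generator": "vsprofile.synthetic", "seed": config.seed,
            "latent": latent,
            "truth": {"family": config.variogram.family,
                      "nugget": config.variogram.nugget,
                      "partial_sill": config.variogram.partial_sill,
                      "range": config.variogram.range_,
                      "mean_level": config.mean_level,
                      "replicate_sd": config.replicate_sd}}
    return VariantDataset(chain_length=config.chain_length, table=df,
                          metadata=meta)


def simulate_dataset(config: SyntheticConfig) -> VariantDataset:
    """Simulate one variant panel; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    return _assemble(config, _draws(config, rng))


def simulate_condition_pair(config: SyntheticConfig, effect: ConditionEffect,
                            treated_condition: str = "drug"
                            ) -> tuple[VariantDataset, VariantDataset]:
    """Simulate basal and treated panels over the same variants.

    The treated ground truth rescales the basal variogram's range by
    ``range_factor`` and its sill (nugget and partial sill together) by
    ``sill_factor`` and shifts the mean by ``mean_shift``, emulating a
    treatment that shortens the spatial correlation range and lowers the
    variance plateau.  With ``shared_seed`` the two conditions reuse the
    same underlying standard-normal draws, so an identity effect yields
    identical latent values.
    """
    rng = np.random.default_rng(config.seed)
    draws = _draws(config, rng)
    basal = _assemble(config, draws)

    base = config.variogram
    treated_model = VariogramModel(
        base.family,
        base.nugget * effect.sill_factor,
        base.partial_sill * effect.sill_factor,
        base.range_ * effect.range_factor
        if base.family != "pure_nugget" else float("nan"))
    treated_cfg = replace(config, variogram=treated_model,
                          mean_level=config.mean_level + effect.mean_shift,
                          condition=treated_condition)
    if effect.shared_seed:
        treated_draws = draws
    else:
        treated_draws = _draws(treated_cfg, np.random.default_rng(
            (config.seed + 0x9E3779B1) % 2**31))
        treated_draws["positions"] = draws["positions"]
        treated_draws["alt_idx"] = draws["alt_idx"]
    treated = _assemble(treated_cfg, treated_draws)
    for ds in (basal, treated):
        ds.metadata["pair_effect"] = {
            "range_factor": effect.range_factor,
            "sill_factor": effect.sill_factor,
            "mean_shift": effect.mean_shift,
            "shared_seed": effect.shared_seed}
    return basal, treated
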