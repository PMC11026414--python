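"""Residue barcodes: inverse-variance-weighted collapse of a landscape.

For each residue column of a masked landscape the high-confidence cells are
aggregated by precision weighting,

    z_hat = sum_i (z_i / sigma_i^2) / sum_i (1 / sigma_i^2),

so confident predictions dominate the per-residue value.  Condition deltas
and activity-to-monomer ratio barcodes are elementwise derivations with NA
propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kriging import LandscapeGrid

_VAR_FLOOR = 1e-12


@dataclass
class ResidueBarcode:
    """One value (or NA) per residue 1..chain_length."""

    chain_length: int
    values: np.ndarray
    n_cells: np.ndarray = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.size != self.chain_length:
            raise ValueError("barcode length must equal chain_length")
        if self.n_cells is None:
            self.n_cells = np.where(np.isfinite(self.values), 1, 0)
        self.n_cells = np.asarray(self.n_cells, int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": np.arange(1, self.chain_length + 1),
                             "value": self.values,
                             "n_cells_used": self.n_cells})


def ivw_barcode(grid: LandscapeGrid, mask: np.ndarray,
                fallback: str = "na") -> ResidueBarcode:
    """Inverse-variance-weighted mean per residue column of a masked grid.

    Cells with variance below 1e-12 get their weight capped at 1e12.  A
    column with no masked cells yields NA under ``fallback='na'`` (with a
    warning counting such residues) or falls back to all cells under
    ``fallback='all'``.
    """
    if mask.shape != grid.variance.shape:
        raise ValueError("mask shape must match the landscape grid")
    if fallback not in ("na", "all"):
        raise ValueError("fallback must be 'na' or 'all'")
    L = grid.chain_length
    values = np.full(L, np.nan)
    n_cells = np.zeros(L, dtype=int)
    n_empty = 0
    w_all = 1.0 / np.maximum(grid.variance, _VAR_FLOOR)
    for col in range(L):
        sel = mask[:, col]
        if not sel.any():
            if fallback == "all":
                sel = np.ones_like(sel)
            else:
                n_empty += 1
                continue
        w = w_all[sel, col]
        z = grid.z_pred[sel, col]
        values[col] = float(np.sum(w * z) / np.sum(w))
        n_cells[col] = int(sel.sum())
    if n_empty:
        warnings.warn(f"{n_empty} residue columns had no high-confidence "
                      "cells; reported as NA")
    return ResidueBarcode(chain_length=L, values=values, n_cells=n_cells,
                          metadata={**grid.metadata, "fallback": fallback,
                                    "n_empty_columns": n_empty})


def delta_barcode(basal: ResidueBarcode, treated: ResidueBarcode,
                  orientation: str = "treated_minus_basal") -> ResidueBarcode:
    """Elementwise condition difference; NA propagates.

    ``treated_minus_basal`` suits phenotypes where an increase is an
    improvement (monomer secretion, inhibitory activity);
    ``basal_minus_treated`` suits polymer loads, so a positive delta always
    reads as improvement.
    """
    if basal.chain_length != treated.chain_length:
        raise ValueError("barcode lengths differ")
    if orientation == "treated_minus_basal":
        d = treated.values - basal.values
    elif orientation == "basal_minus_treated":
        d = basal.values - treated.values
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return ResidueBarcode(chain_length=basal.chain_length, values=d,
                          n_cells=np.minimum(basal.n_cells, treated.n_cells),
                          metadata={"orientation": orientation})


def ratio_barcode(activity: ResidueBarcode, monomer: ResidueBarcode,
                  eps: float = 1e-6) -> ResidueBarcode:
    """Per-residue activity / monomer ratio; monomer <= eps yields NA."""
    if activity.chain_length != monomer.chain_length:
        raise ValueError("barcode lengths differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(monomer.values > eps,
                     activity.values / monomer.values, np.nan)
    return ResidueBarcode(chain_length=activity.chain_length, values=r,
                          n_cells=np.minimum(activity.n_cells,
                                             monomer.n_cells),
                          metadata={"kind": "activity_to_monomer_ratio"})


def ratio_delta_barcode(activity_basal: ResidueBarcode,
                        monomer_basal: ResidueBarcode,
                        activity_treated: ResidueBarcode,
                        monomer_treated: ResidueBarcode,
                        eps: float = 1e-6) -> ResidueBarcode:
    """Treated minus basal activity-to-monomer ratio per residue.

    Ratios are formed from the per-condition IVW barcodes first and then
    differenced (rather than dividing landscape cells before aggregation);
    the convention is recorded in the output metadata.
    """
    rb = ratio_barcode(activity_basal, monomer_basal, eps)
    rt = ratio_barcode(activity_treated, monomer_treated, eps)
    out = delta_barcode(rb, rt, "treated_minus_basal")
    out.metadata["kind"] = "delta_activity_to_monomer_ratio"
    out.metadata["convention"] = "ratio of IVW barcodes, then difference"
    return out
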