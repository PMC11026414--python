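"""Variant-level statistics independent of the kriged landscapes.

Classification follows the field's activity/polymer stratification of
antitrypsin variants: class I (loss of function) below 75% of wild-type
inhibitory activity, class II (impaired) between 75 and 90%, class III
(full activity) above 90%; polymer burden is high above 50% of the Z
polymer reference.  Responder calls use a two-sided pooled-variance
Student's t test on replicate arms, and correlation coefficients are
compared through the Fisher z transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import VariantDataset, _col

ACTIVITY_LOSS = 0.75
ACTIVITY_FULL = 0.90
POLYMER_HIGH = 0.50


@dataclass(frozen=True)
class VariantClass:
    activity_class: str  # I | II | III
    polymer_class: str  # high | low


def classify_variant(activity: float, polymer: float) -> VariantClass:
    """Classify a variant from normalized activity (WT = 1) and polymer
    (Z = 1) levels.

    Boundary values 0.75 and 0.90 fall in class II ("between 75 and 90%");
    polymer exactly at 0.50 is low ("above 50%" defines high).
    """
    if not (np.isfinite(activity) and np.isfinite(polymer)):
        raise ValueError("activity and polymer must be finite")
    if activity < 0 or polymer < 0:
        raise ValueError("activity and polymer must be nonnegative")
    if activity < ACTIVITY_LOSS:
        ac = "I"
    elif activity <= ACTIVITY_FULL:
        ac = "II"
    else:
        ac = "III"
    pc = "high" if polymer > POLYMER_HIGH else "low"
    return VariantClass(ac, pc)


def classify_dataset(dataset: VariantDataset, activity: str, polymer: str,
                     condition: str) -> pd.DataFrame:
    """Per-variant classification table (class x polymer stratum)."""
    act = dataset.table[_col(activity, condition, "mean")].to_numpy(float)
    pol = dataset.table[_col(polymer, condition, "mean")].to_numpy(float)
    rows = []
    for k, label in enumerate(dataset.table["variant"]):
        if not (np.isfinite(act[k]) and np.isfinite(pol[k])):
            continue
        cls = classify_variant(act[k], pol[k])
        rows.append((label, act[k], pol[k], cls.activity_class,
                     cls.polymer_class))
    return pd.DataFrame(rows, columns=["variant", "activity", "polymer",
                                       "activity_class", "polymer_class"])


def responder_test(basal, treated, alpha: float = 0.05) -> dict:
    """Two-sided pooled-variance Student's t test between replicate arms.

    Returns p, the significance call at ``alpha``, the direction of the
    mean change, and a ``degenerate`` flag for the zero-pooled-variance
    corner (equal means give p = 1, unequal means p = 0).
    """
    a = np.asarray(basal, float)
    b = np.asarray(treated, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per arm")
    diff = b.mean() - a.mean()
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
    degenerate = False
    if pooled == 0:
        degenerate = diff != 0
        p = 0.0 if diff != 0 else 1.0
    else:
        _, p = stats.ttest_ind(b, a, equal_var=True)
        p = float(p)
    direction = "increase" if diff > 0 else ("decrease" if diff < 0
                                             else "none")
    return {"p": p, "significant": bool(p < alpha), "direction": direction,
            "degenerate": degenerate}


def responder_table(dataset: VariantDataset, phenotype: str,
                    basal_condition: str, treated_condition: str,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Responder calls for every variant with stored replicates."""
    from .data import get_replicates

    rows = []
    for k, label in enumerate(dataset.table["variant"]):
        a = get_replicates(dataset, phenotype, basal_condition, k)
        b = get_replicates(dataset, phenotype, treated_condition, k)
        if a.size < 2 or b.size < 2:
            continue
        res = responder_test(a, b, alpha)
        rows.append((label, res["p"], res["significant"], res["direction"]))
    return pd.DataFrame(rows, columns=["variant", "p", "significant",
                                       "direction"])


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-sided p for equality of two Pearson correlations via Fisher z.

    The statistic is (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)),
    referred to the standard normal.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 for the Fisher z transform")
    for n in (n1, n2):
        if n < 4:
            raise ValueError("need n >= 4 per correlation")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * stats.norm.sf(abs(z)))
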