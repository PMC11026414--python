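"""Variant tables: naming, normalization conventions, and CSV/TSV I/O.

Conventions follow common practice for serpin variant panels:

* residue positions are 1-based, full-length preprotein numbering (the
  classic Z allele of alpha-1-antitrypsin is E366K on the 418-residue
  chain);
* the spatial x coordinate of a missense variant is position / chain_length,
  so the C-terminal residue sits at x = 1;
* phenotype means are on normalized scales — secreted monomer and protease
  inhibitory activity relative to wild type (WT = 1), polymer loads relative
  to the Z polymer reference (Z = 1).

Columns for measurements follow the grammar
``<phenotype>__<condition>__{mean|sd|n|replicates}`` with replicates stored
as a semicolon-joined list so that a table round-trips through text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
DEFAULT_CHAIN_LENGTH = 418

_MISSENSE_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")
_DEL_POS_RE = re.compile(r"^([A-Z])(\d+)del", re.IGNORECASE)


@dataclass(frozen=True)
class VariantId:
    """Structured protein variant label."""

    label: str
    ref_aa: str | None
    position: int | None
    alt_aa: str | None
    kind: str  # missense | nonsense | deletion | other


def parse_variant_name(label: str) -> VariantId:
    """Parse labels like ``E366K`` (missense), ``Y62*`` (nonsense),
    ``F76del`` (deletion) into a structured id.

    Labels containing ``del`` are deletions; a position is only assigned
    when an amino-acid-plus-position span leads the label (``F76del`` yes,
    nucleotide-style ``1027-1028delTC`` no).  Anything else that does not
    match the missense/nonsense pattern is ``other`` with null fields.
    """
    if not label:
        raise ValueError("empty variant label")
    if "del" in label.lower():
        m = _DEL_POS_RE.match(label)
        if m and m.group(1) in AMINO_ACIDS:
            return VariantId(label, m.group(1), int(m.group(2)), None, "deletion")
        return VariantId(label, None, None, None, "deletion")
    m = _MISSENSE_RE.match(label)
    if m and m.group(1) in AMINO_ACIDS:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if alt == "*":
            return VariantId(label, ref, pos, "*", "nonsense")
        if alt in AMINO_ACIDS:
            return VariantId(label, ref, pos, alt, "missense")
    return VariantId(label, None, None, None, "other")


_MEAS_RE = re.compile(r"^(?P<phen>[^_]+(?:_[^_]+)*?)__(?P<cond>[^_]+(?:_[^_]+)*?)"
                      r"__(?P<stat>mean|sd|n|replicates)$")


@dataclass
class VariantDataset:
    """A variant-phenotype table with normalized coordinates.

    ``table`` carries one row per variant with columns ``variant``,
    ``position`` (nullable), ``x`` (position / chain_length, nan for
    non-missense rows) and measurement columns per the module grammar.
    """

    chain_length: int
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[VariantId]:
        return [parse_variant_name(v) for v in self.table["variant"]]

    def _measurement_keys(self):
        keys = set()
        for col in self.table.columns:
            m = _MEAS_RE.match(col)
            if m:
                keys.add((m.group("phen"), m.group("cond")))
        return keys

    @property
    def phenotypes(self) -> list[str]:
        return sorted({p for p, _ in self._measurement_keys()})

    @property
    def conditions(self) -> list[str]:
        return sorted({c for _, c in self._measurement_keys()})


def _col(phen: str, cond: str, stat: str) -> str:
    return f"{phen}__{cond}__{stat}"


def read_variant_table(path, chain_length: int = DEFAULT_CHAIN_LENGTH,
                       sep: str | None = None) -> VariantDataset:
    """Read a delimited variant table and validate it.

    Requires ``variant`` and ``position`` columns plus at least one
    ``<phenotype>__<condition>__mean`` column (with matching ``sd`` and
    ``n``).  ``x`` is recomputed as position / chain_length for rows whose
    label parses as missense; other rows are loaded but carry x = nan and
    never enter spatial analyses.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    for required in ("variant", "position"):
        if required not in df.columns:
            raise ValueError(f"variant table missing required column "
                             f"{required!r}")
    keys = {( _MEAS_RE.match(c).group("phen"), _MEAS_RE.match(c).group("cond"))
            for c in df.columns if _MEAS_RE.match(c)}
    if not keys:
        raise ValueError("variant table has no <phenotype>__<condition>__mean "
                         "measurement columns")
    for phen, cond in keys:
        for stat in ("mean", "sd", "n"):
            if _col(phen, cond, stat) not in df.columns:
                raise ValueError(f"variant table missing required column "
                                 f"{_col(phen, cond, stat)!r}")
        sd = df[_col(phen, cond, "sd")]
        bad = np.flatnonzero(sd.to_numpy(float) < 0)
        if bad.size:
            raise ValueError(f"negative sd in column "
                             f"{_col(phen, cond, 'sd')!r} at row {bad[0]}")
        nn = df[_col(phen, cond, "n")]
        bad = np.flatnonzero(nn.to_numpy(float) < 1)
        if bad.size:
            raise ValueError(f"replicate count < 1 in column "
                             f"{_col(phen, cond, 'n')!r} at row {bad[0]}")
    df = df.copy()
    df["position"] = pd.array(
        [None if pd.isna(p) else int(p) for p in df["position"]],
        dtype="Int64")
    x = np.full(len(df), np.nan)
    for k, (label, pos) in enumerate(zip(df["variant"], df["position"])):
        vid = parse_variant_name(str(label))
        if vid.kind == "missense":
            p = vid.position if pd.isna(pos) else int(pos)
            x[k] = p / chain_length
    df["x"] = x
    return VariantDataset(chain_length=chain_length, table=df)


def write_variant_table(dataset: VariantDataset, path, sep: str = ",") -> None:
    dataset.table.to_csv(path, sep=sep, index=False)


def replicates_to_str(reps) -> str:
    return ";".join(repr(float(r)) for r in reps)


def replicates_from_str(s) -> np.ndarray:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return np.array([])
    return np.array([float(t) for t in str(s).split(";")])


def get_replicates(dataset: VariantDataset, phenotype: str, condition: str,
                   row: int) -> np.ndarray:
    col = _col(phenotype, condition, "replicates")
    if col not in dataset.table.columns:
        return np.array([])
    return replicates_from_str(dataset.table[col].iloc[row])


def select_spatial(dataset: VariantDataset, phenotype_y: str,
                   phenotype_z: str, condition: str) -> pd.DataFrame:
    """Extract the (x, y, z, sigma_meas) points that feed the variogram.

    Only missense records with finite y and z qualify ("non-spatial" rows —
    nonsense, deletions, wild type — are excluded).  Exact (x, y) duplicates
    are merged by averaging z (merged count recorded in ``n_merged``);
    sigma_meas is the standard error of the z mean, sd / sqrt(n).  Output is
    sorted by x then y.
    """
    for phen in (phenotype_y, phenotype_z):
        if phen not in dataset.phenotypes:
            raise KeyError(f"phenotype {phen!r} not in dataset "
                           f"(has {dataset.phenotypes})")
    if condition not in dataset.conditions:
        raise KeyError(f"condition {condition!r} not in dataset "
                       f"(has {dataset.conditions})")
    tab = dataset.table
    rows = []
    for k, vid in enumerate(dataset.ids):
        if vid.kind != "missense":
            continue
        x = tab["x"].iloc[k]
        yv = tab[_col(phenotype_y, condition, "mean")].iloc[k]
        zv = tab[_col(phenotype_z, condition, "mean")].iloc[k]
        sd = tab[_col(phenotype_z, condition, "sd")].iloc[k]
        nn = tab[_col(phenotype_z, condition, "n")].iloc[k]
        if not (np.isfinite(x) and np.isfinite(yv) and np.isfinite(zv)):
            continue
        rows.append((float(x), float(yv), float(zv),
                     float(sd) / np.sqrt(float(nn))))
    if len(rows) < 3:
        raise ValueError(f"only {len(rows)} spatial points after filtering; "
                         "a variogram needs at least 3")
    df = pd.DataFrame(rows, columns=["x", "y", "z", "sigma_meas"])
    df = (df.groupby(["x", "y"], as_index=False)
            .agg(z=("z", "mean"), sigma_meas=("sigma_meas", "mean"),
                 n_merged=("z", "size")))
    if len(df) < 3:
        raise ValueError("fewer than 3 distinct (x, y) points after merging")
    return df.sort_values(["x", "y"], kind="mergesort").reset_index(drop=True)
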