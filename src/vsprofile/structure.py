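"""Project residue barcodes onto 3D structures via the PDB B-factor field.

Deposited mature-serpin structures are numbered without the signal peptide,
while variant panels use full-length preprotein numbering, so a residue
offset (default 24: preprotein E366K is mature E342K) reconciles the two.
Values are written into columns 61-66 of each ATOM/HETATM record with the
``%6.2f`` format; every other byte of the file is preserved, which is why
this module edits the fixed-column text directly rather than round-tripping
through a structure object.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .barcode import ResidueBarcode

DEFAULT_OFFSET = 24


@dataclass(frozen=True)
class NumberingMap:
    """structure_resnum = full_length_resnum - offset, restricted to one chain.

    ``clamp``, when given, linearly rescales barcode values into that
    (min, max) window before writing if any value falls outside it.
    """

    offset: int = DEFAULT_OFFSET
    chain_id: str | None = None  # None = all chains
    clamp: tuple[float, float] | None = None


def _format_b(value: float) -> str:
    s = f"{value:6.2f}"
    if len(s) > 6:
        raise ValueError(f"value {value} does not fit the B-factor field")
    return s


def write_bfactor_pdb(pdb_in, barcode: ResidueBarcode,
                      numbering: NumberingMap | None = None,
                      pdb_out=None, sentinel: float = 0.0) -> dict:
    """Write per-residue barcode values into the B-factor column.

    ``pdb_in``/``pdb_out`` are paths; ``pdb_out=None`` returns the text in
    the summary instead of writing a file.  Residues absent from the
    barcode (or NA there) receive ``sentinel`` and are listed in the
    summary.  Returns a summary dict with mapped/unmapped residue counts,
    the NA list, and (if requested) the output text.
    """
    numbering = numbering or NumberingMap()
    text = Path(pdb_in).read_text()
    lines = text.splitlines(keepends=True)
    values = barcode.values
    if numbering.clamp is not None:
        finite = values[np.isfinite(values)]
        if finite.size:
            lo, hi = numbering.clamp
            vmin, vmax = float(finite.min()), float(finite.max())
            if vmin < lo or vmax > hi:
                span = vmax - vmin
                scaled = np.where(
                    np.isfinite(values),
                    lo + (values - vmin) / span * (hi - lo) if span > 0
                    else (lo + hi) / 2.0,
                    np.nan)
                values = scaled
    mapped, unmapped, na_residues = set(), set(), set()
    out = []
    for ln, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            out.append(line)
            continue
        if len(line.rstrip("\n")) < 66:
            raise ValueError(f"malformed ATOM record at line {ln}: too short")
        if numbering.chain_id is not None and line[21] != numbering.chain_id:
            out.append(line)
            continue
        try:
            resseq = int(line[22:26])
        except ValueError as e:
            raise ValueError(f"malformed residue number at line {ln}") from e
        full_pos = resseq + numbering.offset
        if 1 <= full_pos <= barcode.chain_length and \
                np.isfinite(values[full_pos - 1]):
            b = values[full_pos - 1]
            mapped.add(resseq)
        else:
            b = sentinel
            if 1 <= full_pos <= barcode.chain_length:
                na_residues.add(full_pos)
            unmapped.add(resseq)
        out.append(line[:60] + _format_b(b) + line[66:])
    if not mapped:
        raise ValueError("no residues of the structure map into the barcode; "
                         "check the numbering offset")
    new_text = "".join(out)
    summary = {"n_mapped": len(mapped), "n_unmapped": len(unmapped),
               "na_residues": sorted(na_residues),
               "offset": numbering.offset}
    if pdb_out is None:
        summary["text"] = new_text
    else:
        Path(pdb_out).write_text(new_text)
    return summary


def read_bfactors(pdb_path_or_text, chain_id: str | None = None) -> dict:
    """Per-residue B-factor (first atom encountered wins); test helper and
    round-trip check for :func:`write_bfactor_pdb`."""
    text = pdb_path_or_text
    p = Path(str(pdb_path_or_text))
    if "\n" not in str(pdb_path_or_text) and p.exists():
        text = p.read_text()
    values = {}
    for line in str(text).splitlines():
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if chain_id is not None and line[21] != chain_id:
            continue
        resseq = int(line[22:26])
        values.setdefault(resseq, float(line[60:66]))
    return values


_BACKBONE = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))


def make_fixture_pdb(n_residues: int, seed: int = 0,
                     chain_id: str = "A") -> str:
    """Minimal single-chain poly-alanine PDB text, deterministic from seed.

    Four backbone atoms (N, CA, C, O) per residue along an extended chain
    with a small seeded jitter; B-factors start at 0.00.
    """
    if n_residues < 1:
        raise ValueError("need at least 1 residue")
    rng = np.random.default_rng(seed)
    lines = []
    serial = 1
    for res in range(1, n_residues + 1):
        base = np.array([3.8 * res, 0.0, 0.0])
        for k, (name, element) in enumerate(_BACKBONE):
            xyz = base + np.array([0.5 * k, 1.2 * (k % 2), 0.0]) \
                + rng.normal(0.0, 0.05, 3)
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} ALA {chain_id}{res:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n")
            serial += 1
    lines.append("END\n")
    return "".join(lines)
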