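"""Per-site structural and evolutionary features.

Two features feed the enrichment analysis: relative solvent accessibility
(RSA), obtained by normalizing an absolute solvent-accessible surface
area (as computed by DSSP) by a residue-type maximum, and the wild-type
residue frequency f_WT (percent) in a column of a multiple sequence
alignment of homologs.

These are conveniences for preparing input tables: the analysis pipeline
normally reads ``rsa`` and ``f_wt`` as precomputed columns.  DSSP itself
and alignment construction are out of scope; this module only parses
their outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

#: Theoretical maximum accessible surface areas (Å²), Tien et al. 2013.
MAX_ASA_TIEN = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Maximum accessible surface areas (Å²) of the Sander–Rost (1994) scale.
MAX_ASA_SANDER = {
    "A": 106.0, "R": 248.0, "N": 157.0, "D": 163.0, "C": 135.0,
    "E": 194.0, "Q": 198.0, "G": 84.0, "H": 184.0, "I": 169.0,
    "L": 164.0, "K": 205.0, "M": 188.0, "F": 197.0, "P": 136.0,
    "S": 130.0, "T": 142.0, "W": 227.0, "Y": 222.0, "V": 142.0,
}

_SCALES = {"tien": MAX_ASA_TIEN, "sander": MAX_ASA_SANDER}

GAP_SYMBOLS = frozenset("-.")


@dataclass(frozen=True)
class AccessibilityRecord:
    """One residue's absolute (Å²) and relative solvent accessibility."""

    residue: str
    asa: float
    rsa: float


@dataclass(frozen=True)
class AlignmentColumn:
    """One alignment column: residues (one-letter, '-' gaps) and the wild type."""

    residues: tuple[str, ...]
    wt_aa: str


def max_asa(residue: str, scale: Literal["tien", "sander"] = "tien") -> float:
    try:
        return _SCALES[scale][residue.upper()]
    except KeyError:
        raise ValueError(f"unknown residue code {residue!r}") from None


def rsa_from_asa(residue: str, asa: float,
                 scale: Literal["tien", "sander"] = "tien") -> float:
    """Relative solvent accessibility: ASA / maxASA(residue), clamped to [0, 1].

    ``scale`` selects the normalization table (theoretical Tien et al.
    values by default, the empirical Sander–Rost scale as alternative).
    """
    if asa < 0:
        raise ValueError(f"ASA must be nonnegative, got {asa}")
    return min(asa / max_asa(residue, scale), 1.0)


def burial_class(rsa: float, cut: float = 0.2) -> str:
    """Classify a residue as ``"buried"`` (RSA <= cut) or ``"exposed"``."""
    if not (0.0 <= rsa <= 1.0):
        raise ValueError(f"rsa must be in [0, 1], got {rsa}")
    return "buried" if rsa <= cut else "exposed"


def wt_frequency(col: AlignmentColumn) -> float:
    """Percent frequency of the wild-type residue in an alignment column.

    Gaps are excluded from the denominator; an all-gap column is an error.
    """
    if not col.residues:
        raise ValueError("empty alignment column")
    non_gap = [r.upper() for r in col.residues if r not in GAP_SYMBOLS]
    if not non_gap:
        raise ValueError("all-gap alignment column")
    return 100.0 * non_gap.count(col.wt_aa.upper()) / len(non_gap)


def read_dssp_accessibility(path: str | Path,
                            scale: Literal["tien", "sander"] = "tien",
                            chain: str | None = None) -> pd.DataFrame:
    """Parse the per-residue ACC column of a DSSP output file.

    Returns a DataFrame with columns ``chain``, ``position``, ``residue``,
    ``asa`` (Å²) and ``rsa`` (normalized with ``scale``).  Non-standard
    residues (including half-cystines, which DSSP writes as lowercase
    letters, mapped back to 'C') are kept; residues without a tabulated
    maximum are dropped.
    """
    from Bio.PDB.DSSP import make_dssp_dict

    dssp, _ = make_dssp_dict(str(path))
    rows = []
    for (ch, res_id), fields in dssp.items():
        if chain is not None and ch != chain:
            continue
        aa, acc = fields[0], fields[2]
        if aa.islower():  # DSSP marks SS-bonded cysteines with lowercase letters
            aa = "C"
        if aa not in MAX_ASA_TIEN:
            continue
        pos = res_id[1]
        rows.append({"chain": ch, "position": int(pos), "residue": aa,
                     "asa": float(acc),
                     "rsa": rsa_from_asa(aa, float(acc), scale)})
    return pd.DataFrame(rows, columns=["chain", "position", "residue", "asa", "rsa"])


def alignment_wt_frequencies(path: str | Path, fmt: str = "fasta",
                             reference_index: int = 0) -> pd.DataFrame:
    """Per-site wild-type residue frequencies from a multiple sequence alignment.

    The reference (wild-type) sequence is the ``reference_index``-th
    alignment row; alignment columns where the reference has a gap are
    skipped, and positions count reference residues 1-based.  Returns a
    DataFrame with ``position``, ``wt_aa`` and ``f_wt`` (percent).
    """
    from Bio import AlignIO

    aln = AlignIO.read(str(path), fmt)
    ref = str(aln[reference_index].seq)
    rows = []
    pos = 0
    for col_idx, wt in enumerate(ref):
        if wt in GAP_SYMBOLS:
            continue
        pos += 1
        column = AlignmentColumn(tuple(str(rec.seq)[col_idx] for rec in aln), wt)
        rows.append({"position": pos, "wt_aa": wt.upper(),
                     "f_wt": wt_frequency(column)})
    return pd.DataFrame(rows, columns=["position", "wt_aa", "f_wt"])


def site_feature_table(protein_id: str, rsa_table: pd.DataFrame,
                       fwt_table: pd.DataFrame) -> pd.DataFrame:
    """Join DSSP RSA and alignment f_WT features keyed by (protein_id, position)."""
    merged = rsa_table.merge(fwt_table, on="position", how="outer")
    merged.insert(0, "protein_id", protein_id)
    return merged.sort_values("position", kind="stable").reset_index(drop=True)
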