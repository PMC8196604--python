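"""Data model, parsing, I/O and filtering for curated missense-variant tables.

The central objects are :class:`VariantRecord` — one single-amino-acid
variant (SAV) with its experimental folding free-energy change (ΔΔG_f,
kcal/mol, positive = destabilizing), optional melting-temperature change
(ΔT_m, °C), a predicted ΔΔG_f, a pathogenicity score in [0, 1], structural
(relative solvent accessibility) and evolutionary (wild-type residue
frequency) features, and a Cancer Mutation Census (CMC) tier annotation —
and :class:`VariantDataset`, an ordered, duplicate-free collection with
filter provenance.

Tables are plain delimited text (comma or tab, auto-detected), UTF-8, with
a mandatory header.  Missing cells stay missing; they are never imputed.
"""

from __future__ import annotations

import csv
import enum
import io
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, one-letter codes.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Fixed column order of the on-disk variant table.
TABLE_COLUMNS = [
    "protein_id",
    "structure_id",
    "variant",
    "ddg_exp",
    "dtm",
    "ddg_pred",
    "patho_score",
    "rsa",
    "f_wt",
    "cmc",
    "n_tumor_samples",
    "is_training",
]

_VARIANT_RE = re.compile(r"^(?:p\.)?([A-Za-z])(\d+)([A-Za-z])$")


class VariantError(ValueError):
    """Raised for malformed variant tokens, records or tables."""


class Cmc(enum.Enum):
    """Cancer Mutation Census annotation tier.

    Tiers 1–3 carry cancer-driver evidence and define putative
    cancer-driving variants (PCVs); ``OTHER`` is treated as benign;
    ``UNANNOTATED`` means the variant is absent from the CMC.
    """

    TIER1 = "Tier 1"
    TIER2 = "Tier 2"
    TIER3 = "Tier 3"
    OTHER = "Other"
    UNANNOTATED = ""

    @classmethod
    def parse(cls, text: str | None) -> "Cmc":
        if text is None:
            return cls.UNANNOTATED
        t = str(text).strip()
        if t == "" or t.lower() in {"na", "nan", "none"}:
            return cls.UNANNOTATED
        norm = t.lower().replace(" ", "").replace("_", "")
        mapping = {
            "tier1": cls.TIER1, "1": cls.TIER1,
            "tier2": cls.TIER2, "2": cls.TIER2,
            "tier3": cls.TIER3, "3": cls.TIER3,
            "other": cls.OTHER,
        }
        if norm not in mapping:
            raise VariantError(f"unrecognized CMC annotation: {text!r}")
        return mapping[norm]

    @property
    def is_annotated(self) -> bool:
        return self is not Cmc.UNANNOTATED

    @property
    def is_driver_tier(self) -> bool:
        return self in (Cmc.TIER1, Cmc.TIER2, Cmc.TIER3)


def parse_variant_notation(token: str) -> tuple[str, int, str]:
    """Parse a protein-level variant token such as ``"p.M1775R"``.

    The ``p.`` prefix is optional on input.  Returns
    ``(wt_aa, position, mut_aa)``.

    Raises
    ------
    VariantError
        If the token is malformed, the position is 0, either residue is
        non-canonical, or wild-type and mutant residues coincide.
    """
    m = _VARIANT_RE.match(str(token).strip())
    if m is None:
        raise VariantError(f"malformed variant token: {token!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if pos < 1:
        raise VariantError(f"variant position must be >= 1 in {token!r}")
    for aa in (wt, mut):
        if aa not in CANONICAL_AA:
            raise VariantError(f"non-canonical residue {aa!r} in {token!r}")
    if wt == mut:
        raise VariantError(f"wild-type and mutant residues coincide in {token!r}")
    return wt, pos, mut


def format_variant(wt_aa: str, position: int, mut_aa: str) -> str:
    """Format a variant triple with the ``p.`` prefix (round-trips the parser)."""
    return f"p.{wt_aa}{position}{mut_aa}"


@dataclass(frozen=True)
class VariantRecord:
    """One missense variant with experimental, predicted and annotation fields.

    ``ddg_exp``/``ddg_pred`` are kcal/mol (positive = destabilizing),
    ``dtm`` is °C, ``patho_score`` and ``rsa`` are fractions in [0, 1],
    ``f_wt`` is a percentage in [0, 100].  Optional numeric fields use
    ``None`` for missing, never 0.
    """

    protein_id: str
    wt_aa: str
    position: int
    mut_aa: str
    ddg_exp: float | None = None
    structure_id: str = ""
    dtm: float | None = None
    ddg_pred: float | None = None
    patho_score: float | None = None
    rsa: float | None = None
    f_wt: float | None = None
    cmc: Cmc = Cmc.UNANNOTATED
    n_tumor_samples: int | None = None
    is_predictor_training: bool = False

    def __post_init__(self) -> None:
        if self.wt_aa not in CANONICAL_AA or self.mut_aa not in CANONICAL_AA:
            raise VariantError(
                f"non-canonical residue in {self.wt_aa}{self.position}{self.mut_aa}")
        if self.wt_aa == self.mut_aa:
            raise VariantError(f"wt == mut at position {self.position}")
        if self.position < 1:
            raise VariantError("position must be >= 1")
        for name, lo, hi in (("patho_score", 0.0, 1.0), ("rsa", 0.0, 1.0),
                             ("f_wt", 0.0, 100.0)):
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise VariantError(f"{name}={v} outside [{lo}, {hi}]")
        if self.n_tumor_samples is not None and self.n_tumor_samples < 0:
            raise VariantError("n_tumor_samples must be nonnegative")

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.protein_id, self.wt_aa, self.position, self.mut_aa)

    @property
    def variant(self) -> str:
        return format_variant(self.wt_aa, self.position, self.mut_aa)


@dataclass(frozen=True)
class VariantDataset:
    """Ordered, duplicate-free collection of variant records with provenance.

    ``provenance`` is the list of filters applied so far (name plus
    parameters); it grows monotonically under filtering, which keeps the
    dataset bookkeeping (e.g. 164 → 97 → 82 records) auditable.
    """

    records: tuple[VariantRecord, ...]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for r in self.records:
            if r.key in seen:
                raise VariantError(
                    f"duplicate variant key: {r.protein_id} {r.variant}")
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def with_filter(self, kept: Iterable[VariantRecord], note: str) -> "VariantDataset":
        return VariantDataset(tuple(kept), self.provenance + (note,))

    def column(self, name: str) -> np.ndarray:
        """Numeric column as a float array with NaN for missing values."""
        vals = [getattr(r, name) for r in self.records]
        return np.array([np.nan if v is None else float(v) for v in vals])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view in the on-disk column layout."""
        rows = []
        for r in self.records:
            rows.append({
                "protein_id": r.protein_id,
                "structure_id": r.structure_id,
                "variant": r.variant,
                "ddg_exp": r.ddg_exp,
                "dtm": r.dtm,
                "ddg_pred": r.ddg_pred,
                "patho_score": r.patho_score,
                "rsa": r.rsa,
                "f_wt": r.f_wt,
                "cmc": r.cmc.value,
                "n_tumor_samples": r.n_tumor_samples,
                "is_training": r.is_predictor_training,
            })
        return pd.DataFrame(rows, columns=TABLE_COLUMNS)

    def protein_groups(self) -> dict[str, "VariantDataset"]:
        """Split by protein_id, preserving record order and provenance."""
        out: dict[str, VariantDataset] = {}
        for pid in dict.fromkeys(r.protein_id for r in self.records):
            recs = tuple(r for r in self.records if r.protein_id == pid)
            out[pid] = VariantDataset(recs, self.provenance + (f"protein:{pid}",))
        return out


def _parse_float(cell: str, column: str, row: int) -> float | None:
    t = cell.strip()
    if t == "" or t.lower() in {"na", "nan", "none"}:
        return None
    try:
        return float(t)
    except ValueError:
        raise VariantError(f"row {row}: cannot parse {column}={cell!r}") from None


def _parse_bool(cell: str) -> bool:
    return str(cell).strip().lower() in {"1", "true", "yes", "y"}


def read_variant_table(path: str | Path | io.TextIOBase) -> VariantDataset:
    """Read a delimited variant table into a :class:`VariantDataset`.

    Comma or tab delimiter is auto-detected from the header line.  Required
    columns: ``protein_id`` and ``variant``; all other columns of
    :data:`TABLE_COLUMNS` are optional and missing cells become missing
    values.  Errors carry the 1-based data row number.
    """
    if isinstance(path, (str, Path)):
        with open(path, "r", encoding="utf-8", newline="") as fh:
            return _read_rows(fh, str(path))
    return _read_rows(path, "<stream>")


def _read_rows(fh, source: str) -> VariantDataset:
    header_line = fh.readline()
    if not header_line:
        raise VariantError(f"{source}: empty file")
    delim = "\t" if header_line.count("\t") >= header_line.count(",") else ","
    rows = csv.reader([header_line.rstrip("\r\n")] + fh.read().splitlines(),
                      delimiter=delim)
    header = next(rows)
    header = [h.strip() for h in header]
    for required in ("protein_id", "variant"):
        if required not in header:
            raise VariantError(f"{source}: missing required column {required!r}")
    idx = {name: header.index(name) for name in header}

    def cell(row: list[str], name: str) -> str:
        i = idx.get(name)
        return row[i] if i is not None and i < len(row) else ""

    records: list[VariantRecord] = []
    for n, row in enumerate(rows, start=1):
        if not any(c.strip() for c in row):
            continue
        try:
            wt, pos, mut = parse_variant_notation(cell(row, "variant"))
            rec = VariantRecord(
                protein_id=cell(row, "protein_id").strip(),
                structure_id=cell(row, "structure_id").strip(),
                wt_aa=wt, position=pos, mut_aa=mut,
                ddg_exp=_parse_float(cell(row, "ddg_exp"), "ddg_exp", n),
                dtm=_parse_float(cell(row, "dtm"), "dtm", n),
                ddg_pred=_parse_float(cell(row, "ddg_pred"), "ddg_pred", n),
                patho_score=_parse_float(cell(row, "patho_score"), "patho_score", n),
                rsa=_parse_float(cell(row, "rsa"), "rsa", n),
                f_wt=_parse_float(cell(row, "f_wt"), "f_wt", n),
                cmc=Cmc.parse(cell(row, "cmc")),
                n_tumor_samples=(
                    None if (c := cell(row, "n_tumor_samples").strip()) == ""
                    else int(float(c))),
                is_predictor_training=_parse_bool(cell(row, "is_training")),
            )
        except VariantError as e:
            raise VariantError(f"{source}: row {n}: {e}") from None
        records.append(rec)
    try:
        return VariantDataset(tuple(records), (f"read:{source}",))
    except VariantError as e:
        raise VariantError(f"{source}: {e}") from None


def write_variant_table(ds: VariantDataset, path: str | Path, sep: str = "\t") -> None:
    """Write the dataset in the standard column layout (``p.`` prefix emitted)."""
    df = ds.to_frame()
    df["is_training"] = df["is_training"].map({True: "1", False: "0"})
    df.to_csv(path, sep=sep, index=False, na_rep="")


def filter_cmc_annotated(ds: VariantDataset) -> VariantDataset:
    """Keep only records with a CMC annotation (Tier 1–3 or "Other")."""
    kept = [r for r in ds if r.cmc.is_annotated]
    logger.info("filter_cmc_annotated: kept %d of %d records", len(kept), len(ds))
    return ds.with_filter(kept, "filter_cmc_annotated")


def exclude_training_variants(ds: VariantDataset) -> VariantDataset:
    """Drop records flagged as used in the pathogenicity predictor's training."""
    kept = [r for r in ds if not r.is_predictor_training]
    logger.info("exclude_training_variants: dropped %d of %d records",
                len(ds) - len(kept), len(ds))
    return ds.with_filter(kept, "exclude_training_variants")


def exclude_variants(
    ds: VariantDataset, keys: Sequence[tuple[str, str]]
) -> VariantDataset:
    """Remove named variants, e.g. ``[("BRCA1", "p.G1788V")]``.

    Each key is ``(protein_id, variant_token)``; unknown keys are an error.
    """
    targets = set()
    for pid, token in keys:
        wt, pos, mut = parse_variant_notation(token)
        targets.add((pid, wt, pos, mut))
    present = {r.key for r in ds}
    unknown = targets - present
    if unknown:
        raise VariantError(f"unknown variant keys: {sorted(unknown)}")
    kept = [r for r in ds if r.key not in targets]
    note = "exclude_variants:" + ",".join(
        f"{p}:{format_variant(w, i, m)}" for p, w, i, m in sorted(targets))
    return ds.with_filter(kept, note)


def label_destabilizing(
    ds: VariantDataset, cut: float = 2.0
) -> tuple[VariantDataset, np.ndarray]:
    """Label highly destabilizing variants: ``ddg_exp > cut`` (strict).

    Records with missing ``ddg_exp`` are dropped (count logged).  Returns
    the restricted dataset and a boolean label array aligned to it.
    A record at exactly the cut is negative.
    """
    kept = [r for r in ds if r.ddg_exp is not None]
    n_dropped = len(ds) - len(kept)
    if n_dropped:
        logger.warning("label_destabilizing: dropped %d records lacking ddg_exp",
                       n_dropped)
    sub = ds.with_filter(kept, f"label_destabilizing:require_ddg_exp(cut={cut})")
    labels = np.array([r.ddg_exp > cut for r in kept], dtype=bool)
    return sub, labels


def label_pcv(ds: VariantDataset) -> np.ndarray:
    """Label putative cancer-driving variants: CMC Tier 1–3 positive, "Other" negative.

    Every record must be CMC-annotated (apply :func:`filter_cmc_annotated`
    first); an unannotated record is a contract violation.
    """
    for r in ds:
        if not r.cmc.is_annotated:
            raise VariantError(
                f"label_pcv: unannotated record {r.protein_id} {r.variant}")
    return np.array([r.cmc.is_driver_tier for r in ds], dtype=bool)
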