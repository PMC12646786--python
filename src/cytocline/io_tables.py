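"""Readers, writers and validation for every table the pipeline touches.

All tab-separated tables carry a header row; missing values are written
as ``NA`` and parsed to an explicit missing state (never silently to 0).
Genomic coordinates are 1-based inclusive internally (GFF3 convention);
BED input is converted on read.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHLOROTYPES = ("PB", "PT", "OTHER", "MISSING")
TRAIT_NAMES = ("gsw", "PhiPSII", "Fs", "Fm", "ETR", "d13C", "Npct")
GARDENS = ("VT", "VA")


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class ValidationError(ValueError):
    """A row violates a field invariant."""


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    contact_zone: str
    lat: float
    lon: float
    chlorotype: str  # PB / PT / OTHER / MISSING
    nuclear_q: float | None  # proportion P. trichocarpa nuclear ancestry
    genotype_id: str

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValidationError(f"{self.sample_id}: lat {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValidationError(f"{self.sample_id}: lon {self.lon} outside [-180, 180]")
        if self.chlorotype not in CHLOROTYPES:
            raise ValidationError(f"{self.sample_id}: chlorotype {self.chlorotype!r}")
        if self.nuclear_q is not None and not (0.0 <= self.nuclear_q <= 1.0):
            raise ValidationError(f"{self.sample_id}: nuclear_q {self.nuclear_q} outside [0,1]")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand {self.strand!r}")


@dataclass(frozen=True)
class ClimateRecord:
    sample_id: str
    TD: float
    MAT: float
    MAP: float
    CMD: float
    RH: float
    PAS: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.RH <= 100.0):
            raise ValidationError(f"{self.sample_id}: RH {self.RH} outside [0,100]")
        for name in ("MAP", "CMD", "PAS"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.sample_id}: {name} negative")


@dataclass(frozen=True)
class TraitRecord:
    genotype_id: str
    garden: str
    block: str
    trait_name: str
    value: float

    def __post_init__(self) -> None:
        if self.garden not in GARDENS:
            raise ValidationError(f"{self.genotype_id}: garden {self.garden!r}")
        if self.trait_name not in TRAIT_NAMES:
            raise ValidationError(f"{self.genotype_id}: trait {self.trait_name!r}")


class AncestryMatrix:
    """Binary haplotype x position local-ancestry matrix.

    Rows are phased haplotypes, two per individual, identified as
    ``<individual>_1`` / ``<individual>_2`` (suffix pattern configurable);
    columns are (chromosome, 1-based position); values are 0 for
    *P. balsamifera* and 1 for *P. trichocarpa* ancestry.
    """

    def __init__(
        self,
        haplotype_ids: Sequence[str],
        positions: Sequence[tuple[str, int]],
        values: np.ndarray,
        suffix_pattern: str = r"_(1|2)$",
    ):
        self.haplotype_ids = list(haplotype_ids)
        self.positions = [(str(c), int(p)) for c, p in positions]
        self.values = np.asarray(values, dtype=np.int8)
        self.suffix_pattern = suffix_pattern
        if self.values.shape != (len(self.haplotype_ids), len(self.positions)):
            raise ValidationError("matrix shape does not match ids/positions")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("ancestry values must be 0 or 1")
        # positions strictly increasing within chromosome
        last: dict[str, int] = {}
        for chrom, pos in self.positions:
            if chrom in last and pos <= last[chrom]:
                raise ValidationError(f"positions not strictly increasing on {chrom}")
            last[chrom] = pos
        self._pair_individuals()

    def _pair_individuals(self) -> None:
        pat = re.compile(self.suffix_pattern)
        groups: dict[str, list[int]] = {}
        for i, hid in enumerate(self.haplotype_ids):
            m = pat.search(hid)
            if not m:
                raise ValidationError(f"haplotype id {hid!r} lacks a _1/_2 suffix")
            groups.setdefault(hid[: m.start()], []).append(i)
        for ind, rows in groups.items():
            if len(rows) != 2:
                raise ValidationError(
                    f"individual {ind!r} has {len(rows)} haplotype rows (need 2)"
                )
        self._individuals = {k: tuple(v) for k, v in sorted(groups.items())}

    @property
    def individual_ids(self) -> list[str]:
        return list(self._individuals)

    def haplotype_rows(self, individual: str) -> tuple[int, int]:
        return self._individuals[individual]

    def individual_proportions(self) -> pd.DataFrame:
        """Per-individual trichocarpa proportion at each position (0, .5, 1)."""
        rows = {
            ind: self.values[list(idx)].mean(axis=0)
            for ind, idx in self._individuals.items()
        }
        cols = [f"{c}:{p}" for c, p in self.positions]
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


_SAMPLE_COLS = ["sample_id", "contact_zone", "lat", "lon", "chlorotype", "nuclear_q", "genotype_id"]
_CLIMATE_COLS = ["sample_id", "TD", "MAT", "MAP", "CMD", "RH", "PAS"]
_TRAIT_COLS = ["genotype_id", "garden", "block", "trait_name", "value"]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
    return df


def _float_or_none(v: Any) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    df = _read_tsv(path, _SAMPLE_COLS)
    records = []
    for i, row in df.iterrows():
        try:
            chlor = row["chlorotype"]
            records.append(
                SampleRecord(
                    sample_id=str(row["sample_id"]),
                    contact_zone=str(row["contact_zone"]),
                    lat=float(row["lat"]),
                    lon=float(row["lon"]),
                    chlorotype="MISSING" if chlor is None or chlor != chlor else str(chlor),
                    nuclear_q=_float_or_none(row["nuclear_q"]),
                    genotype_id=str(row["genotype_id"]),
                )
            )
        except (ValueError, TypeError) as e:
            raise ValidationError(f"{path}: row {i + 2}: {e}") from e
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate sample_id values")
    return records


def read_climate_table(path: str | Path) -> list[ClimateRecord]:
    df = _read_tsv(path, _CLIMATE_COLS)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ClimateRecord(
                    sample_id=str(row["sample_id"]),
                    **{c: float(row[c]) for c in _CLIMATE_COLS[1:]},
                )
            )
        except (ValueError, TypeError) as e:
            raise ValidationError(f"{path}: row {i + 2}: {e}") from e
    return records


def read_trait_table(path: str | Path) -> list[TraitRecord]:
    df = _read_tsv(path, _TRAIT_COLS)
    records = []
    seen: set[tuple] = set()
    for i, row in df.iterrows():
        try:
            rec = TraitRecord(
                genotype_id=str(row["genotype_id"]),
                garden=str(row["garden"]),
                block=str(row["block"]),
                trait_name=str(row["trait_name"]),
                value=float(row["value"]),
            )
        except (ValueError, TypeError) as e:
            raise ValidationError(f"{path}: row {i + 2}: {e}") from e
        key = (rec.genotype_id, rec.garden, rec.block, rec.trait_name)
        if key in seen:
            raise ValidationError(f"{path}: duplicate trait cell {key}")
        seen.add(key)
        records.append(rec)
    return records


def read_ancestry_matrix(path: str | Path, suffix_pattern: str = r"_(1|2)$") -> AncestryMatrix:
    """Read a haplotype x position TSV: first column haplotype id, remaining
    columns named ``chrom:pos``, cells 0/1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    positions = []
    for col in df.columns:
        chrom, _, pos = str(col).rpartition(":")
        if not chrom:
            raise SchemaError(f"{path}: column {col!r} is not 'chrom:pos'")
        positions.append((chrom, int(pos)))
    vals = df.to_numpy()
    bad = ~np.isin(vals, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: cell ({df.index[i]}, {df.columns[j]}) = {vals[i, j]!r} not in {{0,1}}"
        )
    return AncestryMatrix(list(df.index.astype(str)), positions, vals, suffix_pattern)


def write_ancestry_matrix(matrix: AncestryMatrix, path: str | Path) -> None:
    cols = [f"{c}:{p}" for c, p in matrix.positions]
    pd.DataFrame(matrix.values, index=matrix.haplotype_ids, columns=cols).to_csv(
        path, sep="\t", index_label="haplotype"
    )


def read_gene_annotations(path: str | Path, dialect: str) -> list[GeneAnnotation]:
    """Read gene annotations; ``dialect`` is ``"GFF3"`` (1-based inclusive)
    or ``"BED"`` (0-based half-open). Output is always 1-based inclusive."""
    if dialect not in ("GFF3", "BED"):
        raise ValueError(f"unknown dialect {dialect!r}; expected GFF3 or BED")
    annots: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if dialect == "BED":
                if len(f) < 4:
                    raise SchemaError(f"{path}:{lineno}: BED needs >= 4 columns")
                start0, end0 = int(f[1]), int(f[2])
                if end0 <= start0:
                    raise ValidationError(f"{path}:{lineno}: BED end <= start")
                strand = f[5] if len(f) > 5 else "+"
                annots.append(GeneAnnotation(f[3], f[0], start0 + 1, end0, strand))
            else:
                if len(f) < 9:
                    raise SchemaError(f"{path}:{lineno}: GFF3 needs 9 columns")
                if f[2] not in ("gene", "CDS"):
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID") or attrs.get("Name") or f"{f[0]}:{f[3]}-{f[4]}"
                annots.append(GeneAnnotation(gid, f[0], int(f[3]), int(f[4]), f[6]))
    ids = [a.gene_id for a in annots]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate gene_id values")
    return annots


def _records_to_frame(records: Iterable[Any]) -> pd.DataFrame:
    records = list(records)
    if not records:
        return pd.DataFrame()
    first = records[0]
    if dataclasses.is_dataclass(first):
        cols = [f.name for f in dataclasses.fields(first)]
        return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)
    return pd.DataFrame(records)


def _jsonable(v: Any) -> Any:
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, tuple):
        return list(v)
    return v


def write_results(records: Iterable[Any], path: str | Path, format: str = "TSV",
                  columns: Sequence[str] | None = None) -> None:
    """Write dataclass records (or dicts) as TSV or JSON.

    Column order is deterministic (dataclass field order, or the order of
    keys in the first record); floats serialized to 6 significant digits;
    missing values as NA.
    """
    if format not in ("TSV", "JSON"):
        raise ValueError(f"unknown format {format!r}")
    df = _records_to_frame(records)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    if format == "TSV":
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
    else:
        payload = [
            {k: _jsonable(v) for k, v in row.items()}
            for row in df.to_dict(orient="records")
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=_jsonable)
            fh.write("\n")


def write_sample_table(records: Sequence[SampleRecord], path: str | Path) -> None:
    write_results(records, path, "TSV", columns=_SAMPLE_COLS)


def write_gene_annotations(annots: Sequence[GeneAnnotation], path: str | Path,
                           dialect: str = "GFF3", feature: str = "gene") -> None:
    """Write annotations as GFF3 (1-based inclusive) or BED (0-based half-open)."""
    if dialect not in ("GFF3", "BED"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "GFF3":
            fh.write("##gff-version 3\n")
            for a in annots:
                fh.write(
                    f"{a.chromosome}\tcytocline\t{feature}\t{a.start}\t{a.end}\t.\t"
                    f"{a.strand}\t.\tID={a.gene_id}\n"
                )
        else:
            for a in annots:
                fh.write(f"{a.chromosome}\t{a.start - 1}\t{a.end}\t{a.gene_id}\t.\t{a.strand}\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    """Plain multi-FASTA writer (wrapped lines, insertion order preserved)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
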