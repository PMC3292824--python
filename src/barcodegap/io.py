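"""Reading, writing and validation of multi-locus barcode datasets.

A dataset is a set of per-locus aligned multi-FASTA files plus a sample
sheet (TSV) mapping each accession to a species and a locus.  Sequences
are required to be pre-aligned within each locus; no alignment is
computed here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignedRecord",
    "LocusAlignment",
    "SampleSheet",
    "BarcodeDataset",
    "ValidationReport",
    "DatasetError",
    "read_alignment",
    "write_alignment",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_synonym_map",
    "build_dataset",
    "load_dataset",
    "validate_dataset",
]

# Characters legal in an aligned nucleotide sequence: canonical bases,
# IUPAC ambiguity codes, alignment gap, and the two missing-data marks.
_IUPAC_AMBIG = set("RYSWKMBDHV")
_ALLOWED = set("ACGT") | _IUPAC_AMBIG | {"-", "N", "?"}

SHEET_COLUMNS = ("accession_id", "species_label", "locus_name", "source_tag")
SOURCE_TAGS = ("self", "genbank")


class DatasetError(ValueError):
    """Raised when an input file or assembled dataset violates an invariant."""


@dataclass(frozen=True)
class AlignedRecord:
    """One accession's aligned sequence at one locus.

    ``species_label`` is empty until the record is joined against a
    sample sheet (see :func:`build_dataset`).
    """

    accession_id: str
    sequence: str
    species_label: str = ""

    def __post_init__(self) -> None:
        if not self.accession_id:
            raise DatasetError("accession_id must be non-empty")
        if not self.sequence:
            raise DatasetError(f"empty sequence for accession {self.accession_id!r}")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise DatasetError(
                f"accession {self.accession_id!r}: illegal characters {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class LocusAlignment:
    """All accession-level sequences for one locus, column-aligned."""

    locus_name: str
    records: tuple[AlignedRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise DatasetError(f"locus {self.locus_name!r}: no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            offenders = sorted(
                {(r.accession_id, len(r.sequence)) for r in self.records},
                key=lambda t: t[1],
            )
            raise DatasetError(
                f"locus {self.locus_name!r}: unequal aligned lengths "
                f"{sorted(lengths)}; records: {offenders}"
            )
        ids = [r.accession_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"locus {self.locus_name!r}: duplicate accessions {dupes}")

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0].sequence)

    @property
    def accession_ids(self) -> tuple[str, ...]:
        return tuple(r.accession_id for r in self.records)

    def species_labels(self) -> tuple[str, ...]:
        """Distinct species labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.records:
            if r.species_label:
                seen.setdefault(r.species_label, None)
        return tuple(seen)

    def by_species(self) -> dict[str, list[AlignedRecord]]:
        out: dict[str, list[AlignedRecord]] = {}
        for r in self.records:
            out.setdefault(r.species_label, []).append(r)
        return out


@dataclass(frozen=True)
class SampleSheet:
    """Accession → species → locus mapping, one row per (accession, locus)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SHEET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DatasetError(f"sample sheet missing required columns {missing}")
        df = self.frame
        for col in SHEET_COLUMNS:
            blank = df[col].astype(str).str.strip() == ""
            if blank.any():
                raise DatasetError(
                    f"sample sheet: empty {col!r} in rows {list(df.index[blank])}"
                )
        dup = df.duplicated(subset=["accession_id", "locus_name"])
        if dup.any():
            pairs = df.loc[dup, ["accession_id", "locus_name"]].itertuples(index=False)
            raise DatasetError(
                f"sample sheet: duplicate (accession, locus) rows {sorted(map(tuple, pairs))}"
            )
        bad_tag = ~df["source_tag"].isin(SOURCE_TAGS)
        if bad_tag.any():
            raise DatasetError(
                f"sample sheet: source_tag must be one of {SOURCE_TAGS}, got "
                f"{sorted(df.loc[bad_tag, 'source_tag'].unique())}"
            )
        # one species per accession, consistent across loci
        per_acc = df.groupby("accession_id")["species_label"].nunique()
        inconsistent = per_acc[per_acc > 1]
        if not inconsistent.empty:
            raise DatasetError(
                f"sample sheet: accessions with conflicting species labels: "
                f"{sorted(inconsistent.index)}"
            )

    def species_of(self, accession_id: str) -> str:
        sub = self.frame.loc[self.frame["accession_id"] == accession_id, "species_label"]
        if sub.empty:
            raise DatasetError(f"accession {accession_id!r} not in sample sheet")
        return str(sub.iloc[0])

    def loci(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.frame["locus_name"]))

    def species_labels(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.frame["species_label"]))

    def rows_for_locus(self, locus_name: str) -> pd.DataFrame:
        return self.frame[self.frame["locus_name"] == locus_name]

    def apply_synonyms(self, synonym_map: Mapping[str, str]) -> "SampleSheet":
        """Return a sheet with species labels mapped through ``synonym_map``."""
        if not synonym_map:
            return self
        df = self.frame.copy()
        df["species_label"] = df["species_label"].map(lambda s: synonym_map.get(s, s))
        return SampleSheet(df)


@dataclass(frozen=True)
class BarcodeDataset:
    """Validated multi-locus dataset: loci keyed by name plus the sheet."""

    loci: Mapping[str, LocusAlignment]
    sheet: SampleSheet
    synonym_map: Mapping[str, str] = field(default_factory=dict)

    def species_at_locus(self, locus_name: str) -> tuple[str, ...]:
        return self.loci[locus_name].species_labels()

    def locus_names(self) -> tuple[str, ...]:
        return tuple(self.loci)


@dataclass
class ValidationReport:
    """Per-locus counts plus any consistency errors/warnings."""

    per_locus: pd.DataFrame  # locus, n_accessions, n_species, n_singleton_species
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def read_alignment(path: str | Path, locus_name: str) -> LocusAlignment:
    """Parse an aligned multi-FASTA into a :class:`LocusAlignment`.

    The accession id is the first whitespace-delimited token of each
    header.  Sequences are uppercased and RNA ``U`` is mapped to ``T``;
    gaps are preserved.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(AlignedRecord(accession_id=rec.id, sequence=seq))
    if not records:
        raise DatasetError(f"{path}: no FASTA records")
    return LocusAlignment(locus_name=locus_name, records=tuple(records))


def write_alignment(aln: LocusAlignment, path: str | Path) -> None:
    """Write a locus alignment as multi-FASTA (round-trips with read_alignment)."""
    recs = [
        SeqRecord(Seq(r.sequence), id=r.accession_id, description="")
        for r in aln.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read the tab-separated sample sheet, trimming surrounding whitespace."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: sample sheet missing columns {missing}")
    for col in SHEET_COLUMNS:
        df[col] = df[col].str.strip()
    return SampleSheet(df[list(SHEET_COLUMNS)])


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_synonym_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (alias, canonical) → dict."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise DatasetError(f"{path}: synonym row needs 2 columns, got {row!r}")
            out[row[0].strip()] = row[1].strip()
    return out


def build_dataset(
    loci: Iterable[LocusAlignment],
    sheet: SampleSheet,
    synonym_map: Mapping[str, str] | None = None,
) -> BarcodeDataset:
    """Join alignments against the sheet, annotating species labels.

    The synonym map (alias → canonical) is applied to species labels at
    this point, merging synonymous species.  Every aligned accession must
    appear in the sheet for its locus.
    """
    synonym_map = dict(synonym_map or {})
    sheet = sheet.apply_synonyms(synonym_map)
    out: dict[str, LocusAlignment] = {}
    for aln in loci:
        rows = sheet.rows_for_locus(aln.locus_name)
        lookup = dict(zip(rows["accession_id"], rows["species_label"]))
        annotated = []
        for rec in aln.records:
            label = lookup.get(rec.accession_id)
            if label is None:
                raise DatasetError(
                    f"locus {aln.locus_name!r}: accession {rec.accession_id!r} "
                    "absent from sample sheet"
                )
            annotated.append(replace(rec, species_label=label))
        out[aln.locus_name] = LocusAlignment(aln.locus_name, tuple(annotated))
    return BarcodeDataset(loci=out, sheet=sheet, synonym_map=synonym_map)


def load_dataset(
    data_dir: str | Path,
    sheet_name: str = "samples.tsv",
    synonym_name: str = "synonyms.tsv",
) -> BarcodeDataset:
    """Load ``<data_dir>/<locus>.fasta`` for every locus named in the sheet."""
    data_dir = Path(data_dir)
    sheet = read_sample_sheet(data_dir / sheet_name)
    synonyms: dict[str, str] = {}
    if (data_dir / synonym_name).exists():
        synonyms = read_synonym_map(data_dir / synonym_name)
    alns = []
    for locus in sheet.loci():
        fasta = data_dir / f"{locus}.fasta"
        if not fasta.exists():
            raise DatasetError(f"missing alignment file {fasta}")
        alns.append(read_alignment(fasta, locus))
    return build_dataset(alns, sheet, synonyms)


def validate_dataset(ds: BarcodeDataset) -> ValidationReport:
    """Cross-check alignments against the sheet; count species per locus.

    Singleton species (exactly one accession at a locus) are reported so
    that intra-specific statistics can exclude them.
    """
    errors: list[str] = []
    warnings: list[str] = []
    if not ds.loci:
        raise DatasetError("dataset has no loci")
    rows = []
    sheet_keys = set(
        zip(ds.sheet.frame["accession_id"], ds.sheet.frame["locus_name"])
    )
    seen_keys: set[tuple[str, str]] = set()
    for name, aln in ds.loci.items():
        by_sp = aln.by_species()
        n_singleton = sum(1 for recs in by_sp.values() if len(recs) == 1)
        rows.append(
            {
                "locus": name,
                "n_accessions": len(aln.records),
                "n_species": len(by_sp),
                "n_singleton_species": n_singleton,
            }
        )
        for rec in aln.records:
            key = (rec.accession_id, name)
            seen_keys.add(key)
            if key not in sheet_keys:
                errors.append(
                    f"locus {name!r}: accession {rec.accession_id!r} not in sheet"
                )
    for acc, locus in sorted(sheet_keys - seen_keys):
        warnings.append(f"sheet row ({acc!r}, {locus!r}) has no aligned sequence")
    per_locus = pd.DataFrame(rows).set_index("locus")
    return ValidationReport(per_locus=per_locus, errors=errors, warnings=warnings)
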