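"""Readers/writers for the standard formats the pipeline touches.

Sequence formats go through Biopython; the pipeline's own tabular
artifacts (tag tables, T-plot data, summaries) are plain TSV with a
single commented header line starting with ``#``.

Coordinates are 0-based half-open internally and 1-based inclusive in
everything user-facing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A malformed input file."""


@dataclass
class FastaRecord:
    id: str
    description: str
    sequence: str


@dataclass
class TagTable:
    """Collapsed small-RNA tags: unique sequences with per-library counts.

    ``counts`` is a DataFrame indexed by sequence with one integer column
    per declared library.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("tag sequences must be unique")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        self.counts = self.counts.astype("int64")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sequences(self) -> list[str]:
        return list(self.counts.index)

    def __len__(self) -> int:
        return len(self.counts)

    def total(self, sequence: str) -> int:
        """Summed raw count of one tag across all libraries."""
        return int(self.counts.loc[sequence].sum())

    def library_totals(self) -> dict[str, int]:
        return {lib: int(v) for lib, v in self.counts.sum(axis=0).items()}

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[str, Mapping[str, int]]], libraries: Sequence[str]
    ) -> "TagTable":
        libs = list(libraries)
        data: dict[str, list[int]] = {}
        for seq, counts in rows:
            missing = set(libs) - set(counts)
            if missing:
                raise ValueError(f"tag {seq!r} missing counts for {sorted(missing)}")
            row = [int(counts[lib]) for lib in libs]
            if seq in data:
                warnings.warn(f"duplicate tag {seq!r}: counts summed", stacklevel=2)
                data[seq] = [a + b for a, b in zip(data[seq], row)]
            else:
                data[seq] = row
        df = pd.DataFrame.from_dict(data, orient="index", columns=libs, dtype="int64")
        df.index.name = "sequence"
        return cls(df)


@dataclass
class Interval:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    cls: str
    source: str = "user"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval start must be < end ({self.start}, {self.end})")
        if self.cls not in ANNOTATION_CLASSES:
            raise ValueError(f"unknown annotation class {self.cls!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


ANNOTATION_CLASSES = ("rRNAetc", "repeat", "exon", "intron")


@dataclass
class AnnotationTrack:
    """Genomic intervals carrying one annotation class each; may overlap."""

    intervals: list[Interval] = field(default_factory=list)

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read FASTA records, order-preserving, sequences uppercased.

    U and T are both accepted and preserved as given (modulo case).
    """
    path = Path(path)
    text = path.read_text()
    _validate_fasta_lines(text, path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(FastaRecord(rec.id, rec.description, str(rec.seq).upper()))
    return records


def _validate_fasta_lines(text: str, path: Path) -> None:
    in_record = False
    header_line = 0
    has_seq = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if in_record and not has_seq:
                raise FormatError(f"{path}:{header_line}: record with empty sequence")
            if stripped == ">":
                raise FormatError(f"{path}:{lineno}: malformed FASTA header")
            in_record = True
            header_line = lineno
            has_seq = False
        else:
            if not in_record:
                raise FormatError(f"{path}:{lineno}: sequence before any FASTA header")
            has_seq = True
    if in_record and not has_seq:
        raise FormatError(f"{path}:{header_line}: record with empty sequence")


def write_fasta(records: Iterable[FastaRecord], path: str | Path, width: int = 60) -> None:
    """Write FASTA with canonical wrapping (default 60 columns)."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=_desc_tail(r)) for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def _desc_tail(r: FastaRecord) -> str:
    # Biopython prints "id description"; strip a duplicated id.
    if r.description.startswith(r.id):
        return r.description[len(r.id) :].strip()
    return r.description


def read_tag_table(path: str | Path, libraries: Sequence[str] | None = None) -> TagTable:
    """Read a collapsed tag table: TSV with header ``sequence<TAB>lib...``."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if header.startswith("#"):
        header = header[1:].lstrip()
    cols = header.split("\t")
    if not cols or cols[0] != "sequence":
        raise FormatError(f"{path}: first header column must be 'sequence'")
    file_libs = cols[1:]
    if libraries is not None and list(libraries) != file_libs:
        raise FormatError(
            f"{path}: header libraries {file_libs} do not match declared {list(libraries)}"
        )
    df = pd.read_csv(path, sep="\t", comment=None, skiprows=1, header=None, names=cols)
    for lib in file_libs:
        col = df[lib]
        if col.isna().any():
            raise FormatError(f"{path}: missing count in column {lib}")
        as_int = col.astype("float64")
        if ((as_int % 1) != 0).any() or (as_int < 0).any():
            raise FormatError(f"{path}: counts must be non-negative integers ({lib})")
    rows = [
        (str(r["sequence"]).upper(), {lib: int(r[lib]) for lib in file_libs})
        for _, r in df.iterrows()
    ]
    return TagTable.from_rows(rows, file_libs)


def write_tag_table(table: TagTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#sequence\t" + "\t".join(table.libraries) + "\n")
        for seq, row in table.counts.iterrows():
            fh.write(seq + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def collapse_fastq(path: str | Path, library: str = "lib1") -> TagTable:
    """Collapse a FASTQ file into a one-library tag table.

    Reads are uppercased before collapsing; the total of the counts equals
    the number of FASTQ records.
    """
    counts: dict[str, int] = {}
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            seq = str(rec.seq).upper()
            counts[seq] = counts.get(seq, 0) + 1
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return TagTable.from_rows(((s, {library: c}) for s, c in counts.items()), [library])


def write_tplot_data(
    site_profile: Mapping[int, int],
    predicted_site: int,
    path: str | Path,
    transcript_length: int | None = None,
) -> None:
    """Write T-plot data: (position, abundance, is_predicted_site) TSV.

    Positions are 1-based on the transcript. The predicted site row is
    emitted even at zero abundance.
    """
    if not site_profile:
        raise ValueError("empty degradome profile")
    length = transcript_length if transcript_length is not None else max(site_profile)
    if not 1 <= predicted_site <= length:
        raise ValueError(
            f"predicted site {predicted_site} outside transcript (length {length})"
        )
    positions = sorted(set(site_profile) | {predicted_site})
    with open(path, "w") as fh:
        fh.write("#position\tabundance\tis_predicted_site\n")
        for pos in positions:
            flag = 1 if pos == predicted_site else 0
            fh.write(f"{pos}\t{int(site_profile.get(pos, 0))}\t{flag}\n")


def read_tracks_bed(path: str | Path, cls_field: int = 3, source: str = "user") -> AnnotationTrack:
    """Read annotation intervals from BED (class taken from the name field)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) <= cls_field:
                raise FormatError(f"{path}:{lineno}: too few BED columns")
            strand = parts[5] if len(parts) > 5 else "+"
            intervals.append(
                Interval(parts[0], int(parts[1]), int(parts[2]), strand, parts[cls_field], source)
            )
    return AnnotationTrack(intervals)
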