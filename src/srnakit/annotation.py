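"""Small-RNA tag annotation by a fixed priority rule.

Every clean tag receives exactly one category following
``rRNAetc (GenBank > Rfam) > known miRNA > repeat > exon > intron``;
anything left is ``unann``. Sequence-database classes (rRNAetc, miRNA)
are assigned by sequence match to the class database; interval classes
(repeat, exon, intron) require a genome hit overlapping the interval
(any >=1-nt overlap, either strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import revcomp, to_dna
from .io_formats import AnnotationTrack, TagTable

PRIORITY = ("rRNAetc", "miRNA", "repeat", "exon", "intron")
CATEGORIES = PRIORITY + ("unann",)


@dataclass(frozen=True)
class GenomeHit:
    chrom: str
    start: int  # 0-based, plus-strand leftmost coordinate
    strand: str


@dataclass
class AnnotatedTag:
    sequence: str
    counts: dict[str, int]
    category: str
    genome_hits: list[GenomeHit] = field(default_factory=list)
    matched_source: str = "none"


def length_filter(
    tags: TagTable, min_len: int = 18, max_len: int = 28
) -> tuple[TagTable, dict[str, int]]:
    """Keep tags with min_len <= length <= max_len (inclusive bounds).

    Returns the filtered table and a report of the removed mass
    (``removed_unique``, ``removed_total``).
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    import numpy as np

    lengths = np.array([len(s) for s in tags.counts.index], dtype=int)
    keep = (lengths >= min_len) & (lengths <= max_len)
    removed = tags.counts.loc[~keep]
    report = {
        "removed_unique": int((~keep).sum()),
        "removed_total": int(removed.values.sum()),
    }
    return TagTable(tags.counts.loc[keep].copy()), report


def match_genome(
    tags: TagTable | Iterable[str],
    genome: Mapping[str, str],
    max_mismatches: int = 0,
) -> dict[str, list[GenomeHit]]:
    """Exact genome hits of every tag, both strands.

    A tag "matches the genome" iff it has at least one hit. Only exact
    matching is supported.
    """
    if max_mismatches != 0:
        raise NotImplementedError("only exact genome matching is supported")
    seqs = tags.sequences if isinstance(tags, TagTable) else list(tags)
    genome_dna = {c: to_dna(s) for c, s in genome.items()}
    hits: dict[str, list[GenomeHit]] = {}
    for seq in seqs:
        fwd = to_dna(seq)
        rev = revcomp(fwd)
        found: list[GenomeHit] = []
        for chrom, cseq in genome_dna.items():
            for query, strand in ((fwd, "+"), (rev, "-")):
                pos = cseq.find(query)
                while pos != -1:
                    found.append(GenomeHit(chrom, pos, strand))
                    pos = cseq.find(query, pos + 1)
        hits[seq] = found
    return hits


def _overlaps_class(
    hit: GenomeHit, tag_len: int, intervals_by_chrom: Mapping[str, list], cls: str
) -> bool:
    for iv in intervals_by_chrom.get(hit.chrom, ()):
        if iv.cls != cls:
            continue
        if hit.start < iv.end and iv.start < hit.start + tag_len:
            return True
    return False


def annotate(
    tags: TagTable,
    tracks: AnnotationTrack,
    known_mirna_db: Iterable[str],
    structural_db: Mapping[str, str] | None = None,
    genome_hits: Mapping[str, list[GenomeHit]] | None = None,
) -> tuple[list[AnnotatedTag], pd.DataFrame]:
    """Assign each tag its single highest-priority category.

    ``known_mirna_db`` holds mature (and optionally precursor) sequences;
    a tag is in the miRNA class when it matches one exactly (U/T
    equivalent) or is contained in a precursor entry. ``structural_db``
    maps structural-RNA sequences (rRNA/tRNA/sn(o)RNA) to their source
    ("GenBank" or "Rfam"); GenBank outranks Rfam for the reported source.
    Interval classes need ``genome_hits``.
    """
    mirna_set = {to_dna(s) for s in known_mirna_db}
    structural = {to_dna(s): src for s, src in (structural_db or {}).items()}
    by_chrom = tracks.by_chrom()
    genome_hits = genome_hits or {}

    annotated: list[AnnotatedTag] = []
    for seq in tags.sequences:
        dna = to_dna(seq)
        hits = list(genome_hits.get(seq, ()))
        category, source = "unann", "none"
        struct_srcs = {
            src for s, src in structural.items() if dna == s or dna in s or s in dna
        }
        # also honour rRNAetc intervals when supplied on a track
        if not struct_srcs and hits and any(
            _overlaps_class(h, len(seq), by_chrom, "rRNAetc") for h in hits
        ):
            struct_srcs = {"user"}
        if struct_srcs:
            category = "rRNAetc"
            source = ("GenBank" if "GenBank" in struct_srcs
                      else "Rfam" if "Rfam" in struct_srcs else "user")
        elif dna in mirna_set or any(dna in p for p in mirna_set if len(p) > len(dna)):
            category, source = "miRNA", "miRBase"
        else:
            for cls in ("repeat", "exon", "intron"):
                if any(_overlaps_class(h, len(seq), by_chrom, cls) for h in hits):
                    category, source = cls, "user"
                    break
        annotated.append(
            AnnotatedTag(
                sequence=seq,
                counts={lib: int(c) for lib, c in tags.counts.loc[seq].items()},
                category=category,
                genome_hits=hits,
                matched_source=source,
            )
        )
    return annotated, summarize(annotated, tags.libraries)


def summarize(annotated: Sequence[AnnotatedTag], libraries: Sequence[str]) -> pd.DataFrame:
    """Data-set summary in the bookkeeping layout: per-category unique and
    total read counts with percentages of clean reads, plus clean-read and
    genome-match rows."""
    rows = {}
    clean_unique = len(annotated)
    clean_total = {lib: 0 for lib in libraries}
    for t in annotated:
        for lib in libraries:
            clean_total[lib] += t.counts.get(lib, 0)

    def row(tags_subset):
        uniq = len(tags_subset)
        tot = {lib: sum(t.counts.get(lib, 0) for t in tags_subset) for lib in libraries}
        return uniq, tot

    categories = {
        "Match genome": [t for t in annotated if t.genome_hits],
        "miRNA": [t for t in annotated if t.category == "miRNA"],
        "Match GenBank/Rfam": [t for t in annotated if t.category == "rRNAetc"],
        "repeat": [t for t in annotated if t.category == "repeat"],
        "exon": [t for t in annotated if t.category == "exon"],
        "intron": [t for t in annotated if t.category == "intron"],
        "unann": [t for t in annotated if t.category == "unann"],
    }
    rows["Clean reads"] = (clean_unique, clean_total)
    rows.update({name: row(sub) for name, sub in categories.items()})

    out = []
    for name, (uniq, tot) in rows.items():
        rec = {"category": name, "unique": uniq}
        rec["unique_pct"] = 100.0 * uniq / clean_unique if clean_unique else 0.0
        for lib in libraries:
            rec[f"total_{lib}"] = tot[lib]
        rec["total"] = sum(tot.values())
        total_clean = sum(clean_total.values())
        rec["total_pct"] = 100.0 * rec["total"] / total_clean if total_clean else 0.0
        out.append(rec)
    return pd.DataFrame(out).set_index("category")


def length_distribution(
    annotated: Sequence[AnnotatedTag],
    by: str = "all",
    min_len: int = 18,
    max_len: int = 28,
) -> dict[int, tuple[int, int]]:
    """Histogram length -> (unique tags, total reads) over the clean-read
    size range; ``by="miRNA"`` restricts to tags in the miRNA category."""
    if by not in ("all", "miRNA"):
        raise ValueError(f"unknown selector {by!r}")
    hist: dict[int, tuple[int, int]] = {}
    for t in annotated:
        if by == "miRNA" and t.category != "miRNA":
            continue
        n = len(t.sequence)
        if not min_len <= n <= max_len:
            continue
        u, tot = hist.get(n, (0, 0))
        hist[n] = (u + 1, tot + sum(t.counts.values()))
    return hist
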