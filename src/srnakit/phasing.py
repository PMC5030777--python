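"""PHAS locus and phasiRNA detection from 21-nt tags.

A phased locus produces 21-nt siRNAs whose 5' ends fall on a fixed
21-nt register downstream of a miRNA cleavage site; antisense members
sit 2 nt behind the sense register (the duplex-overhang geometry), so
antisense starts are shifted by +2 onto the sense register before
counting. Windows of ``cycles`` phase lengths are scored with a
hypergeometric tail:

    population  = 2 x phase x cycles   (all starts, both strands)
    successes   = 2 x cycles           (register starts, both strands)
    draws       = n observed distinct (strand, start) positions
    P           = P(X >= k), k = observed in-register positions

Loci with k >= 3 and P at or below the cutoff (default 1e-4) are
reported; overlapping significant windows merge keeping the minimum-P
window's coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .annotation import GenomeHit, match_genome
from .io_formats import TagTable

ANTISENSE_OFFSET = 2  # nt; duplex 3'-overhang geometry


@dataclass
class PhasedLocus:
    chrom: str
    start: int  # 0-based window start
    end: int  # half-open
    strand_register: int  # register position (= start)
    n: int  # distinct (strand, shifted start) positions in window
    k: int  # positions in phase
    p_value: float
    phasirnas: list[str] = field(default_factory=list)
    triggers: list[tuple[str, int, float]] = field(default_factory=list)


def phasing_pvalue(k: int, n: int, phase: int = 21, cycles: int = 11) -> float:
    """Hypergeometric tail P(X >= k) for k in-register draws out of n."""
    if phase <= 0:
        raise ValueError("phase must be > 0")
    if cycles < 2:
        raise ValueError("cycles must be >= 2")
    population = 2 * phase * cycles
    successes = 2 * cycles
    if n > population or k > n:
        raise ValueError("invalid (k, n) for the window size")
    return float(hypergeom.sf(k - 1, population, successes, n))


def _effective_positions(
    tag_hits: Mapping[str, list[GenomeHit]], tag_lengths: Mapping[str, int]
) -> dict[str, list[tuple[int, str, str]]]:
    """Per chromosome: (shifted start, strand, tag sequence) triples.

    Sense tags keep their 5' start; antisense tags are shifted +2 onto
    the sense register.
    """
    out: dict[str, list[tuple[int, str, str]]] = {}
    for seq, hits in tag_hits.items():
        for h in hits:
            pos = h.start if h.strand == "+" else h.start + ANTISENSE_OFFSET
            out.setdefault(h.chrom, []).append((pos, h.strand, seq))
    return out


def detect_phasirnas(
    tags: TagTable | Mapping[str, int],
    genome: Mapping[str, str],
    phase: int = 21,
    cycles: int = 11,
    cutoff: float = 1e-4,
    min_k: int = 3,
    genome_hits: Mapping[str, list[GenomeHit]] | None = None,
) -> list[PhasedLocus]:
    """Scan phase x cycles windows anchored at observed tag starts.

    Only tags of exactly ``phase`` nt enter the analysis; tags that do
    not match the genome are discarded.
    """
    if phase <= 0:
        raise ValueError("phase must be > 0")
    if cycles < 2:
        raise ValueError("cycles must be >= 2")
    seqs = tags.sequences if isinstance(tags, TagTable) else list(tags)
    seqs = [s for s in seqs if len(s) == phase]
    if genome_hits is None:
        genome_hits = match_genome(seqs, genome)
    else:
        genome_hits = {s: genome_hits.get(s, []) for s in seqs}
    span = phase * cycles
    loci: list[PhasedLocus] = []
    for chrom, triples in _effective_positions(genome_hits, {s: len(s) for s in seqs}).items():
        distinct = sorted({(pos, strand) for pos, strand, _ in triples})
        anchors = sorted({pos for pos, _ in distinct})
        for a in anchors:
            inside = [(p, s) for p, s in distinct if a <= p < a + span]
            n = len(inside)
            k = sum(1 for p, _ in inside if (p - a) % phase == 0)
            if k < min_k:
                continue
            p_val = phasing_pvalue(k, n, phase, cycles)
            if p_val > cutoff:
                continue
            members = sorted(
                {
                    seq
                    for pos, strand, seq in triples
                    if a <= pos < a + span and (pos - a) % phase == 0
                }
            )
            loci.append(
                PhasedLocus(
                    chrom=chrom,
                    start=a,
                    end=a + span,
                    strand_register=a,
                    n=n,
                    k=k,
                    p_value=p_val,
                    phasirnas=members,
                )
            )
    return merge_overlapping(loci)


def merge_overlapping(loci: Sequence[PhasedLocus]) -> list[PhasedLocus]:
    """Merge overlapping significant windows, keeping the minimum-P
    window's coordinates (and statistics)."""
    by_chrom: dict[str, list[PhasedLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    merged: list[PhasedLocus] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda l: l.start)
        cluster: list[PhasedLocus] = []
        end = -1
        for locus in group:
            if cluster and locus.start < end:
                cluster.append(locus)
                end = max(end, locus.end)
            else:
                if cluster:
                    merged.append(min(cluster, key=lambda l: (l.p_value, l.start)))
                cluster = [locus]
                end = locus.end
        if cluster:
            merged.append(min(cluster, key=lambda l: (l.p_value, l.start)))
    return merged


def count_phasirnas(locus: PhasedLocus) -> int:
    """Distinct member tags at phased registers."""
    return len(set(locus.phasirnas))


def link_triggers(
    loci: Iterable[PhasedLocus],
    target_alignments: Iterable,
    transcript_locations: Mapping[str, tuple[str, int]] | None = None,
    phase: int = 21,
) -> list[PhasedLocus]:
    """Attach miRNA triggers whose degradome-supported cleavage site falls
    within a locus window extended by one phase on each side.

    ``transcript_locations`` maps transcript id -> (chrom, 0-based
    genomic start of transcript position 1); when omitted, transcript
    ids are taken as chromosome names with genomic 1-based coordinates.
    """
    out = list(loci)
    for aln in target_alignments:
        if transcript_locations is not None:
            loc = transcript_locations.get(aln.transcript)
            if loc is None:
                continue
            chrom, offset = loc
            site = offset + aln.cleavage_position - 1  # 0-based genomic
        else:
            chrom, site = aln.transcript, aln.cleavage_position - 1
        for locus in out:
            if locus.chrom != chrom:
                continue
            if locus.start - phase <= site < locus.end + phase:
                locus.triggers.append((aln.mirna, aln.cleavage_position, aln.score))
    for locus in out:
        locus.triggers.sort(key=lambda t: (t[2], t[0]))
    return out
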