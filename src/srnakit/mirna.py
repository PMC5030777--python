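"""Known-miRNA identification and novel-miRNA prediction.

Known miRNAs follow the four tag2miRNA-style steps: fuzzy alignment of
tags to a reference miRNA database (<=2 mismatches, <=3 gaps), election
of one highest-expressed representative per family, ungapped
re-quantification against the representatives (<=2 mismatches), and a
hairpin check of the precursor.

Novel miRNAs follow MIREAP-style structural criteria evaluated on a
minimum-free-energy fold of the candidate precursor: single-hairpin
structure with the mature wholly in one arm, a star sequence with 2-nt
3' overhangs at both duplex ends, no internal loop or bulge in the
duplex larger than a configurable maximum (default 5 nt), MFE at or
below -18 kcal/mol, a summed mature count of at least 5, and the star
observed in the sequenced tags.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import RNA

from ._seq import is_iupac, revcomp, to_dna
from .io_formats import TagTable


# ---------------------------------------------------------------------------
# hairpin folding and evaluation
# ---------------------------------------------------------------------------

@dataclass
class HairpinStructure:
    """An MFE secondary structure of a candidate precursor."""

    sequence: str
    structure: str  # dot-bracket
    mfe: float  # kcal/mol
    pairs: list[int | None]  # partner index per position, None if unpaired

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.sequence):
            raise ValueError("structure/sequence length mismatch")


def _pair_table(structure: str) -> list[int | None]:
    pairs: list[int | None] = [None] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pairs


def fold_hairpin(sequence: str, min_len: int = 50, max_len: int = 400) -> HairpinStructure:
    """Deterministic MFE fold of a candidate precursor (ViennaRNA)."""
    if not is_iupac(sequence):
        raise ValueError("sequence contains non-IUPAC characters")
    if not min_len <= len(sequence) <= max_len:
        raise ValueError(
            f"precursor length {len(sequence)} outside [{min_len}, {max_len}]"
        )
    structure, mfe = RNA.fold(sequence.upper().replace("T", "U"))
    return HairpinStructure(sequence.upper(), structure, float(mfe), _pair_table(structure))


def _mature_partners(hp: HairpinStructure, ms: int, me: int) -> list[int]:
    return [hp.pairs[i] for i in range(ms, me) if hp.pairs[i] is not None]


def is_single_hairpin(hp: HairpinStructure, mature: tuple[int, int]) -> bool:
    """Mature lies in one arm of a stem with a single terminal loop.

    ``mature`` is a 0-based half-open interval on the precursor. Fails if
    the mature spans the loop, is unpaired, or a multiloop separates the
    mature from its pairing partner region.
    """
    ms, me = mature
    if not (0 <= ms < me <= len(hp.sequence)):
        raise ValueError("mature interval outside precursor")
    partners = _mature_partners(hp, ms, me)
    if not partners:
        return False
    if not (all(p >= me for p in partners) or all(p < ms for p in partners)):
        return False  # mature spans the loop
    five_prime_arm = partners[0] >= me
    # innermost (loop-proximal) paired mature base and its partner
    if five_prime_arm:
        inner = max(i for i in range(ms, me) if hp.pairs[i] is not None)
        lo, hi = inner, hp.pairs[inner]
    else:
        inner = min(i for i in range(ms, me) if hp.pairs[i] is not None)
        lo, hi = hp.pairs[inner], inner
    # the enclosed region must contain at most one terminal loop
    enclosed = hp.structure[lo + 1 : hi]
    n_loops = len(re.findall(r"\(\.*\)", enclosed))
    return n_loops <= 1


def check_star_overhang(
    hp: HairpinStructure, mature: tuple[int, int]
) -> tuple[int, int] | None:
    """Star interval implied by the fold, with 2-nt 3' overhangs.

    Returns a 0-based half-open interval on the precursor, or None when
    the folded pairing cannot support a canonical 2-nt-overhang duplex
    (mature spanning the loop, unpaired anchors, blunt ends at the
    precursor boundary, or mature end bases pairing into the star).
    """
    ms, me = mature
    if me - ms < 5:
        raise ValueError("mature too short")
    if not is_single_hairpin(hp, mature):
        return None
    a5, a3 = hp.pairs[ms], hp.pairs[me - 3]
    if a5 is None or a3 is None:
        return None
    s_lo, s_hi = a3, a5 + 2  # inclusive bounds; identical formula for both arms
    if s_lo > s_hi:
        return None
    if s_lo < 0 or s_hi >= len(hp.sequence):
        return None  # no room for the overhang: blunt precursor end
    if not (s_hi < ms or s_lo >= me):
        return None  # star overlaps mature
    # the mature 3'-overhang bases must not pair into the star
    for p in (me - 2, me - 1):
        q = hp.pairs[p]
        if q is not None and s_lo <= q <= s_hi:
            return None
    return (s_lo, s_hi + 1)


def max_duplex_bulge(hp: HairpinStructure, mature: tuple[int, int]) -> int:
    """Largest internal loop/bulge side within the mature-anchored duplex."""
    ms, me = mature
    paired = [i for i in range(ms, me) if hp.pairs[i] is not None]
    if len(paired) < 2:
        return me - ms
    worst = 0
    for i, j in zip(paired, paired[1:]):
        gap_q = j - i - 1
        gap_t = abs(hp.pairs[i] - hp.pairs[j]) - 1
        worst = max(worst, gap_q, gap_t)
    # unpaired run at either mature end also counts as a bulge
    worst = max(worst, paired[0] - ms, me - 1 - paired[-1])
    return worst


@dataclass
class HairpinEvaluation:
    """Per-criterion outcome of the structural novel-miRNA checks."""

    hairpin: HairpinStructure
    mature: tuple[int, int]
    hairpin_ok: bool
    star: tuple[int, int] | None
    star_ok: bool
    max_bulge: int
    bulge_ok: bool
    mfe_ok: bool

    @property
    def passed(self) -> bool:
        return self.hairpin_ok and self.star_ok and self.bulge_ok and self.mfe_ok

    @property
    def star_sequence(self) -> str | None:
        if self.star is None:
            return None
        return self.hairpin.sequence[self.star[0] : self.star[1]]


def evaluate_hairpin(
    precursor: str,
    mature: tuple[int, int],
    mfe_max: float = -18.0,
    max_bulge: int = 5,
    min_len: int = 50,
    max_len: int = 400,
) -> HairpinEvaluation:
    """Fold a precursor and apply the structural criteria to one mature."""
    hp = fold_hairpin(precursor, min_len=min_len, max_len=max_len)
    hairpin_ok = is_single_hairpin(hp, mature)
    star = check_star_overhang(hp, mature) if hairpin_ok else None
    bulge = max_duplex_bulge(hp, mature) if hairpin_ok else len(precursor)
    return HairpinEvaluation(
        hairpin=hp,
        mature=mature,
        hairpin_ok=hairpin_ok,
        star=star,
        star_ok=star is not None,
        max_bulge=bulge,
        bulge_ok=bulge <= max_bulge,
        mfe_ok=hp.mfe <= mfe_max,
    )


# ---------------------------------------------------------------------------
# known-miRNA identification
# ---------------------------------------------------------------------------

@dataclass
class MirbaseEntry:
    name: str
    family: str
    sequence: str  # mature or precursor
    kind: str = "mature"  # mature | precursor


@dataclass
class FamilyAssignment:
    family: str
    mismatches: int
    gaps: int


def _mm_gap_align(
    query: str, ref: str, max_mm: int, max_gaps: int
) -> tuple[int, int] | None:
    """(mismatches, gaps) of the minimum-edit fit of ``query`` inside ``ref``.

    Semi-global: the query aligns end-to-end, start/end free in the
    reference. The alignment minimises total edits (mismatch and gap both
    cost 1, ties broken toward fewer mismatches); the budgets are then
    checked on that optimal alignment, so substitutions cannot be traded
    away for pairs of gaps. Returns None when either budget is exceeded.
    """
    q, r = to_dna(query), to_dna(ref)
    nq = len(q)
    INF = (10**9, 10**9)
    # dp[i] = lexicographic-minimal (total edits, mismatches) for query
    # prefix i at the current reference column
    prev = [(g, 0) for g in range(nq + 1)]
    best = prev[nq]
    for rc in r:
        cur = [(0, 0)]  # free start in the reference
        for i in range(1, nq + 1):
            sub = 0 if q[i - 1] == rc else 1
            t, m = prev[i - 1]
            cand = (t + sub, m + sub)  # (mis)match
            t, m = prev[i]
            cand = min(cand, (t + 1, m))  # gap in query (skip ref base)
            t, m = cur[i - 1]
            cand = min(cand, (t + 1, m))  # gap in ref (skip query base)
            cur.append(cand)
        best = min(best, cur[nq])
        prev = cur
    total, mm = best
    gaps = total - mm
    if mm > max_mm or gaps > max_gaps:
        return None
    return (mm, gaps)


def align_to_mirbase(
    tag: str,
    db: Sequence[MirbaseEntry],
    max_mismatches: int = 2,
    max_gaps: int = 3,
) -> list[FamilyAssignment]:
    """All family assignments of one tag within the edit budgets, best-first."""
    seen: dict[str, tuple[int, int]] = {}
    for entry in db:
        hit = _mm_gap_align(tag, entry.sequence, max_mismatches, max_gaps)
        if hit is None:
            continue
        old = seen.get(entry.family)
        if old is None or (hit[0] + hit[1], hit[0]) < (old[0] + old[1], old[0]):
            seen[entry.family] = hit
    out = [FamilyAssignment(f, mm, g) for f, (mm, g) in seen.items()]
    out.sort(key=lambda a: (a.mismatches + a.gaps, a.mismatches, a.family))
    return out


def build_family_representatives(
    assignments: Mapping[str, Iterable[str]], tags: TagTable
) -> dict[str, str]:
    """One representative tag per family: highest summed count, ties broken
    toward the lexicographically smaller sequence.

    ``assignments`` maps tag sequence -> families it was assigned to.
    """
    reps: dict[str, tuple[int, str]] = {}
    for seq, families in assignments.items():
        total = tags.total(seq)
        for fam in families:
            cur = reps.get(fam)
            if cur is None or (-total, seq) < (-cur[0], cur[1]):
                reps[fam] = (total, seq)
    return {fam: seq for fam, (_, seq) in reps.items()}


def _ungapped_mismatches(tag: str, rep: str) -> int | None:
    """Min mismatches over full-containment ungapped offsets; None if impossible."""
    a, b = to_dna(tag), to_dna(rep)
    if len(a) > len(b):
        a, b = b, a
    best = None
    for off in range(len(b) - len(a) + 1):
        mm = sum(1 for x, y in zip(a, b[off : off + len(a)]) if x != y)
        if best is None or mm < best:
            best = mm
    return best


def quantify_known(
    tags: TagTable,
    temp_db: Mapping[str, str],
    max_mismatches: int = 2,
) -> dict[str, dict[str, int]]:
    """Per-representative raw counts per library.

    Each tag contributes to at most one representative: its best match by
    mismatch count, ties broken toward the representative with the higher
    own expression, then by family name.
    """
    rep_expr = {
        fam: (tags.total(seq) if seq in tags.counts.index else 0)
        for fam, seq in temp_db.items()
    }
    counts: dict[str, dict[str, int]] = {
        fam: {lib: 0 for lib in tags.libraries} for fam in temp_db
    }
    for seq in tags.sequences:
        best: tuple[int, int, str] | None = None  # (mm, -rep_expr, family)
        for fam, rep in temp_db.items():
            mm = _ungapped_mismatches(seq, rep)
            if mm is None or mm > max_mismatches:
                continue
            key = (mm, -rep_expr[fam], fam)
            if best is None or key < best:
                best = key
        if best is not None:
            fam = best[2]
            for lib, c in tags.counts.loc[seq].items():
                counts[fam][lib] += int(c)
    return counts


def merge_replicates(
    identified: Mapping[str, Iterable[str]],
    groups: Mapping[str, Sequence[str]],
    policy: str = "both",
) -> dict[str, set[str]]:
    """Genotype-level presence calls: a miRNA is reported for a group iff
    identified in every replicate library of that group."""
    if policy != "both":
        raise ValueError(f"unknown policy {policy!r}")
    out: dict[str, set[str]] = {}
    for name, libs in identified.items():
        libset = set(libs)
        present = {g for g, members in groups.items() if set(members) <= libset}
        out[name] = present
    return out


# ---------------------------------------------------------------------------
# novel-miRNA prediction
# ---------------------------------------------------------------------------

@dataclass
class MiRNARecord:
    name: str
    mature: str
    star: str | None
    precursor: str
    arm: str  # 5p | 3p
    chrom: str
    start: int  # 0-based genomic start of the precursor window
    strand: str
    counts: dict[str, int] = field(default_factory=dict)
    status: str = "novel"
    mfe: float = 0.0
    structure: str = ""


def _cluster_hits(
    hits: Mapping[str, list], max_gap: int = 100
) -> list[tuple[str, str, int, int, list[str]]]:
    """Group genome hits of tags into (chrom, strand, start, end, members)."""
    placed: list[tuple[str, str, int, int, str]] = []
    for seq, seq_hits in hits.items():
        for h in seq_hits:
            placed.append((h.chrom, h.strand, h.start, h.start + len(seq), seq))
    placed.sort(key=lambda x: (x[0], x[1], x[2]))
    clusters: list[tuple[str, str, int, int, list[str]]] = []
    for chrom, strand, start, end, seq in placed:
        if clusters and clusters[-1][0] == chrom and clusters[-1][1] == strand and start - clusters[-1][3] <= max_gap:
            c = clusters[-1]
            clusters[-1] = (chrom, strand, c[2], max(c[3], end), c[4] + [seq])
        else:
            clusters.append((chrom, strand, start, end, [seq]))
    return clusters


_WINDOW_LENGTHS = (80, 90, 100, 120, 150, 200, 250, 300)
_UPSTREAM_OFFSETS = (0, 5, 10, 20)


def predict_novel(
    tags: TagTable,
    genome: Mapping[str, str],
    genome_hits: Mapping[str, list],
    min_count: int = 5,
    mfe_max: float = -18.0,
    max_bulge: int = 5,
    require_star: bool = True,
    name_prefix: str = "miRN",
) -> list[MiRNARecord]:
    """MIREAP-style novel miRNA calls from candidate tag clusters.

    ``genome_hits`` maps candidate tag sequences to their genome hits
    (see :func:`srnakit.annotation.match_genome`); candidates should be
    unannotated genome-matching tags plus intron/antisense-exon tags.
    For each cluster the highest-count tag is the mature candidate; a
    grid of excision windows around the cluster is folded and the first
    window satisfying every structural criterion is kept.
    """
    tag_seqs = {to_dna(s) for s in tags.sequences}
    records: list[MiRNARecord] = []
    seen_loci: list[tuple[str, str, int, int]] = []  # a hairpin matches both strands
    n = 0
    for chrom, strand, cstart, cend, members in _cluster_hits(genome_hits):
        mature = max(set(members), key=lambda s: (tags.total(s), s))
        if tags.total(mature) < min_count:
            continue
        mhits = [h for h in genome_hits[mature] if h.chrom == chrom and h.strand == strand and cstart <= h.start < cend]
        if not mhits:
            continue
        mstart = mhits[0].start
        mlen = len(mature)
        chrom_seq = genome[chrom]
        found = None
        for length in _WINDOW_LENGTHS:
            for up in _UPSTREAM_OFFSETS:
                for anchor in (cstart - up, cend + up - length):
                    wstart = max(0, anchor)
                    wend = min(len(chrom_seq), wstart + length)
                    if wend - wstart < 50:
                        continue
                    if not (wstart <= mstart and mstart + mlen <= wend):
                        continue
                    window = chrom_seq[wstart:wend]
                    if strand == "-":
                        precursor = revcomp(window)
                        pms = wend - (mstart + mlen)
                    else:
                        precursor = window
                        pms = mstart - wstart
                    ev = evaluate_hairpin(
                        precursor,
                        (pms, pms + mlen),
                        mfe_max=mfe_max,
                        max_bulge=max_bulge,
                        max_len=max(_WINDOW_LENGTHS) + 1,
                    )
                    if not ev.passed:
                        continue
                    star_seq = ev.star_sequence
                    if require_star and (star_seq is None or to_dna(star_seq) not in tag_seqs):
                        continue
                    found = (wstart, precursor, pms, ev, star_seq)
                    break
                if found:
                    break
            if found:
                break
        if not found:
            continue
        wstart, precursor, pms, ev, star_seq = found
        wend = wstart + len(precursor)
        mat_dna = to_dna(mature)
        if any(
            kc == chrom and km == mat_dna and wstart < e and s < wend
            for kc, km, s, e in seen_loci
        ):
            continue
        seen_loci.append((chrom, to_dna(mature), wstart, wend))
        n += 1
        arm = "5p" if pms < len(precursor) - (pms + mlen) else "3p"
        records.append(
            MiRNARecord(
                name=f"{name_prefix}{n:02d}",
                mature=mature,
                star=star_seq,
                precursor=precursor,
                arm=arm,
                chrom=chrom,
                start=wstart,
                strand=strand,
                counts={lib: int(c) for lib, c in tags.counts.loc[mature].items()},
                status="novel",
                mfe=ev.hairpin.mfe,
                structure=ev.hairpin.structure,
            )
        )
    return records
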