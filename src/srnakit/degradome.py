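"""Degradome (PARE) target calling.

Degradome tags are 5' ends of uncapped 3' cleavage fragments; a peak of
tag 5' ends on a transcript, opposite positions 10/11 of a
complementary miRNA, evidences miRNA-guided cleavage. Complementarity
is scored with Allen-style rules (mismatch 1.0, G:U 0.5, gap 1.0,
penalties doubled at miRNA positions 2-13); a pair is a target when the
score is no more than 4.5. Sites are then ranked into categories 0-4 by
how the degradome abundance at the site compares with the transcript-
wide maximum and median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Sequence

from ._seq import revcomp, to_dna


@dataclass
class DegradomeProfile:
    """Per-transcript degradome tag 5'-end abundances (1-based positions)."""

    transcript: str
    length: int
    abundance: dict[int, int]

    def __post_init__(self) -> None:
        for pos, a in self.abundance.items():
            if not 1 <= pos <= self.length:
                raise ValueError(f"position {pos} outside transcript [1, {self.length}]")
            if a < 1:
                raise ValueError("stored abundances must be >= 1")


@dataclass
class AlignmentColumn:
    mirna_pos: int | None  # 1-based, 5'->3'; None for a gap in the miRNA
    target_idx: int | None  # 0-based index in revcomp(window); None for a gap
    kind: str  # match | wobble | mismatch | gap


@dataclass
class TargetAlignment:
    mirna: str
    transcript: str
    score: float
    columns: list[AlignmentColumn] = field(default_factory=list)
    cleavage_position: int = 0  # 1-based transcript coordinate
    category: int = -1
    fragment_abundance: int = 0


DEFAULT_SCORING = {
    "mismatch": 1.0,
    "gu": 0.5,
    "gap": 1.0,
    "core": (2, 13),
    "core_multiplier": 2.0,
}


def _column_kind(m_base: str, rc_base: str) -> str:
    # rc_base is from the reverse-complemented target window, so a
    # perfect miRNA:target pair shows as identity; G:U wobble between
    # miRNA and target shows as (G, A) or (T, C) here.
    if m_base == rc_base:
        return "match"
    if (m_base, rc_base) in (("G", "A"), ("T", "C")):
        return "wobble"
    return "mismatch"


def _weight(mirna_pos: int, scoring: Mapping) -> float:
    lo, hi = scoring["core"]
    return scoring["core_multiplier"] if lo <= mirna_pos <= hi else 1.0


def score_alignment(
    mirna: str,
    site_sequence: str,
    scoring: Mapping | None = None,
) -> TargetAlignment:
    """Score miRNA vs. a candidate target window (both given 5'->3').

    The window is reverse-complemented and globally aligned to the miRNA
    with gaps allowed; perfect Watson-Crick complementarity scores 0.
    """
    if not mirna or not site_sequence:
        raise ValueError("empty miRNA or site sequence")
    sc = dict(DEFAULT_SCORING, **(scoring or {}))
    q = to_dna(mirna)
    t = to_dna(revcomp(site_sequence))
    n, m = len(q), len(t)
    INF = float("inf")
    dp = [[INF] * (m + 1) for _ in range(n + 1)]
    back: list[list[str]] = [[""] * (m + 1) for _ in range(n + 1)]
    dp[0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            cur = dp[i][j]
            if cur == INF:
                continue
            if i < n and j < m:
                kind = _column_kind(q[i], t[j])
                pen = {"match": 0.0, "wobble": sc["gu"], "mismatch": sc["mismatch"]}[kind]
                cost = cur + pen * (_weight(i + 1, sc) if pen else 1.0)
                if cost < dp[i + 1][j + 1]:
                    dp[i + 1][j + 1] = cost
                    back[i + 1][j + 1] = "D"
            if i < n:  # gap in target
                cost = cur + sc["gap"] * _weight(i + 1, sc)
                if cost < dp[i + 1][j]:
                    dp[i + 1][j] = cost
                    back[i + 1][j] = "U"
            if j < m:  # gap in miRNA
                cost = cur + sc["gap"] * _weight(min(i + 1, n), sc)
                if cost < dp[i][j + 1]:
                    dp[i][j + 1] = cost
                    back[i][j + 1] = "L"
    # traceback
    cols: list[AlignmentColumn] = []
    i, j = n, m
    while i > 0 or j > 0:
        move = back[i][j]
        if move == "D":
            i, j = i - 1, j - 1
            cols.append(AlignmentColumn(i + 1, j, _column_kind(q[i], t[j])))
        elif move == "U":
            i -= 1
            cols.append(AlignmentColumn(i + 1, None, "gap"))
        else:
            j -= 1
            cols.append(AlignmentColumn(None, j, "gap"))
    cols.reverse()
    return TargetAlignment(mirna=mirna, transcript="", score=dp[n][m], columns=cols)


def predict_cleavage(
    alignment: TargetAlignment,
    window_start: int,
    window_length: int,
    transcript_length: int | None = None,
) -> int:
    """Transcript coordinate (1-based) pairing miRNA position 10 — the
    5'-most nucleotide of the downstream cleavage fragment.

    ``window_start`` is the 1-based transcript coordinate of the window's
    5' end.
    """
    if transcript_length is not None and (
        window_start < 1 or window_start + window_length - 1 > transcript_length
    ):
        raise ValueError("target window partially outside transcript")
    for col in alignment.columns:
        if col.mirna_pos == 10 and col.target_idx is not None:
            return window_start + (window_length - 1 - col.target_idx)
    raise ValueError("miRNA position 10 is not aligned to a target base")


def classify_category(profile: DegradomeProfile | Mapping[int, int], site: int) -> int:
    """Category 0-4 of a supported cleavage site.

    4: site abundance is exactly one raw read; 0: unique transcript-wide
    maximum; 1: shared maximum; 2: above the median (of positions with
    >=1 read) but not a maximum; 3: at or below the median.
    """
    abundance = profile.abundance if isinstance(profile, DegradomeProfile) else dict(profile)
    a = abundance.get(site, 0)
    if a < 1:
        raise ValueError(f"site {site} has no degradome reads")
    if a == 1:
        return 4
    values = list(abundance.values())
    mx = max(values)
    med = median(values)
    if a == mx:
        return 0 if values.count(mx) == 1 else 1
    return 2 if a > med else 3


def preprocess_degradome(
    tags: Mapping[str, int],
    structural_db: Mapping[str, str] | None = None,
    polyn_fraction: float = 0.7,
) -> tuple[dict[str, int], dict[str, str]]:
    """Remove structural-RNA and polyN degradome tags.

    Tags are reannotated by the Rfam > GenBank > polyN priority; a polyN
    tag has one base making up strictly more than ``polyn_fraction`` of
    its length. Returns (surviving tags, removal ledger seq -> reason).
    """
    structural = {to_dna(s): src for s, src in (structural_db or {}).items()}
    survivors: dict[str, int] = {}
    ledger: dict[str, str] = {}
    for seq, count in tags.items():
        dna = to_dna(seq)
        srcs = {src for s, src in structural.items() if dna == s or dna in s}
        if "Rfam" in srcs:
            ledger[seq] = "Rfam"
        elif "GenBank" in srcs:
            ledger[seq] = "GenBank"
        elif max(dna.count(b) for b in "ACGT") > polyn_fraction * len(dna):
            ledger[seq] = "polyN"
        else:
            survivors[seq] = count
    return survivors, ledger


def call_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    profiles: Mapping[str, DegradomeProfile],
    max_score: float = 4.5,
    scoring: Mapping | None = None,
) -> list[TargetAlignment]:
    """Score every degradome-supported candidate site of every
    (miRNA, transcript) pair; keep pairs with score <= max_score.

    Candidate windows are placed so the supported position pairs miRNA
    position 10 (ungapped placement). Output is sorted by
    (miRNA, category, score).
    """
    results: list[TargetAlignment] = []
    for tid, profile in profiles.items():
        seq = transcripts.get(tid)
        if seq is None:
            continue
        for name, mirna in mirnas.items():
            L = len(mirna)
            best: TargetAlignment | None = None
            for pos in profile.abundance:
                wstart = pos - (L - 10)  # 1-based window start
                if wstart < 1 or wstart + L - 1 > len(seq):
                    continue
                window = seq[wstart - 1 : wstart - 1 + L]
                aln = score_alignment(mirna, window, scoring)
                if aln.score > max_score:
                    continue
                aln.mirna = name
                aln.transcript = tid
                aln.cleavage_position = predict_cleavage(aln, wstart, L, len(seq))
                aln.fragment_abundance = profile.abundance.get(aln.cleavage_position, 0)
                if aln.fragment_abundance < 1:
                    continue
                aln.category = classify_category(profile, aln.cleavage_position)
                if best is None or (aln.category, aln.score) < (best.category, best.score):
                    best = aln
            if best is not None:
                results.append(best)
    results.sort(key=lambda a: (a.mirna, a.category, a.score))
    return results
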