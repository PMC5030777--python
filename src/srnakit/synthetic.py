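"""Synthetic data with the statistical structure the pipeline assumes.

Generates toy genomes carrying plantable miRNA hairpin loci, multi-
library collapsed sRNA tag tables (two genotype groups with replicate
Poisson sampling and log-normal locus abundances), degradome profiles
realisable in every cleavage-site category, and 21-nt phased loci.
Every generator is a pure function of (config, seed): the same seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._seq import revcomp
from .io_formats import TagTable

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int = 1
    n_replicates: int = 2  # libraries per group
    groups: tuple[str, str] = ("MT", "WT")
    genome_length: int = 60_000
    n_mirna_loci: int = 12
    n_phas_loci: int = 2
    mature_length: int = 21
    phase_length: int = 21
    read_length_range: tuple[int, int] = (18, 28)
    expression_meanlog: float = 4.0  # log-scale mean of locus abundance
    expression_sdlog: float = 1.2  # heavy tail: many low, few high loci
    noise_tag_rate: float = 0.3  # fraction of background rows in the table
    star_fraction: float = 0.15  # star abundance relative to mature
    fold_change_injections: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 18 <= self.mature_length <= 24:
            raise ValueError("mature_length must be within [18, 24]")
        if any(f <= 0 for f in self.fold_change_injections.values()):
            raise ValueError("injected fold-change factors must be > 0")

    @property
    def libraries(self) -> list[str]:
        return [f"{g}_bio{i + 1}" for g in self.groups for i in range(self.n_replicates)]


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


@dataclass
class MirnaLocusTruth:
    name: str
    precursor: str
    mature: str
    star: str
    arm: str
    mature_offset: int  # 0-based within precursor
    star_offset: int
    chrom: str = ""
    start: int = -1  # 0-based genomic start of precursor
    strand: str = "+"


def gen_mirna_locus(
    config: SimConfig,
    arm: str = "5p",
    mature_seq: str | None = None,
    seed: int | None = None,
    name: str = "locus",
    overhang: int = 2,
    bulge_in_duplex: int = 0,
    mature_offset: int = 3,
    stem_ext: int = 10,
    loop_length: int = 12,
    gc: float = 0.55,
) -> MirnaLocusTruth:
    """Construct a hairpin precursor with a planted mature/star duplex.

    The two arms are perfectly reverse-complementary (apart from an
    optional planted duplex bulge of ``bulge_in_duplex`` nt); the planted
    star carries a 3' overhang of ``overhang`` nt (2 = canonical duplex
    geometry, 0 = blunt) at both duplex ends.
    """
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")
    if mature_offset < overhang:
        raise ValueError(
            f"cannot satisfy a {overhang}-nt overhang with mature_offset={mature_offset}"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m = config.mature_length
    if mature_seq is not None and len(mature_seq) != m:
        raise ValueError("mature_seq length must equal config.mature_length")
    o = mature_offset
    S = o + m + stem_ext
    arm5 = list(_random_seq(rng, S, gc))
    if arm == "5p" and mature_seq is not None:
        arm5[o : o + m] = list(mature_seq.upper().replace("U", "T"))
    loop = _random_seq(rng, loop_length, gc=0.3)
    if arm == "3p" and mature_seq is not None:
        # plant the mature on the 3' arm: overwrite the complement region
        arm5[o : o + m] = list(revcomp(mature_seq.upper().replace("U", "T")))
    arm3 = revcomp("".join(arm5))
    precursor = "".join(arm5) + loop + arm3
    N = len(precursor)
    if arm == "5p":
        ms = o
        star_lo = N - o - m + overhang
    else:
        ms = N - o - m
        star_lo = o + overhang
    mature = precursor[ms : ms + m]
    star = precursor[star_lo : star_lo + m]
    if bulge_in_duplex > 0:
        # insert a bulge on the stem side opposite the mature interior
        if arm == "5p":
            at = N - 1 - (o + m // 2)
        else:
            at = o + m // 2
            ms += bulge_in_duplex
        insert = _random_seq(rng, bulge_in_duplex, gc=0.2)
        precursor = precursor[:at] + insert + precursor[at:]
        mature = precursor[ms : ms + m]
    return MirnaLocusTruth(
        name=name,
        precursor=precursor,
        mature=mature,
        star=star,
        arm=arm,
        mature_offset=ms,
        star_offset=star_lo if bulge_in_duplex == 0 else -1,
    )


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: dict[str, str]
    loci: list[MirnaLocusTruth]
    tags: TagTable


def gen_genome(
    config: SimConfig, loci: Sequence[MirnaLocusTruth], chrom: str = "chr1"
) -> tuple[dict[str, str], list[MirnaLocusTruth]]:
    """Random genome with the precursors embedded at evenly spaced sites."""
    rng = np.random.default_rng(config.seed + 101)
    seq = list(_random_seq(rng, config.genome_length))
    placed = []
    if loci:
        spacing = config.genome_length // (len(loci) + 1)
        for i, locus in enumerate(loci):
            start = spacing * (i + 1)
            if start + len(locus.precursor) > config.genome_length:
                raise ValueError("genome too short for the requested loci")
            seq[start : start + len(locus.precursor)] = list(locus.precursor)
            placed.append(replace(locus, chrom=chrom, start=start, strand="+"))
    return {chrom: "".join(seq)}, placed


def gen_srna_libraries(
    config: SimConfig, truth: Sequence[MirnaLocusTruth]
) -> TagTable:
    """Collapsed tag table over both genotype groups.

    Locus abundance is log-normal across loci; replicate counts are
    Poisson around the per-group mean; ``fold_change_injections``
    multiply the MT-group mean of the named loci; random background tags
    are added at ``noise_tag_rate``.
    """
    rng = np.random.default_rng(config.seed + 202)
    libs = config.libraries
    rows: list[tuple[str, dict[str, int]]] = []
    for locus in truth:
        base = float(rng.lognormal(config.expression_meanlog, config.expression_sdlog))
        factor = config.fold_change_injections.get(locus.name, 1.0)
        means = {"MT": base * factor, "WT": base}
        mature_counts = {}
        star_counts = {}
        for lib in libs:
            group = lib.split("_")[0]
            mu = means.get(group, base)
            mature_counts[lib] = int(rng.poisson(mu))
            star_counts[lib] = int(rng.poisson(mu * config.star_fraction))
        rows.append((locus.mature, mature_counts))
        if locus.star:
            rows.append((locus.star, star_counts))
    n_truth = len(rows)
    rate = config.noise_tag_rate
    n_noise = int(round(rate / (1.0 - rate) * n_truth)) if 0 < rate < 1 else 0
    lo, hi = config.read_length_range
    for _ in range(n_noise):
        length = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, length)
        counts = {lib: int(rng.poisson(2.0) + 1) for lib in libs}
        rows.append((seq, counts))
    # collisions between random tags and truth tags are summed by contract
    merged: dict[str, dict[str, int]] = {}
    for seq, counts in rows:
        if seq in merged:
            for lib in libs:
                merged[seq][lib] += counts[lib]
        else:
            merged[seq] = dict(counts)
    return TagTable.from_rows(merged.items(), libs)


def simulate(config: SimConfig) -> SimulatedDataset:
    """End-to-end dataset: loci, genome with embedded precursors, tags."""
    rng = np.random.default_rng(config.seed)
    loci = []
    for i in range(config.n_mirna_loci):
        arm = "5p" if i % 2 == 0 else "3p"
        loci.append(
            gen_mirna_locus(
                config,
                arm=arm,
                seed=int(rng.integers(0, 2**31 - 1)),
                name=f"locus{i + 1:02d}",
            )
        )
    genome, placed = gen_genome(config, loci)
    tags = gen_srna_libraries(config, placed)
    return SimulatedDataset(config=config, genome=genome, loci=placed, tags=tags)


def gen_degradome_profile(
    transcript_length: int,
    true_site: int,
    signal: int,
    background: int,
    category: int = 0,
    n_background: int = 10,
    seed: int = 1,
) -> dict[int, int]:
    """Degradome 5'-end profile realising a requested category at the site.

    ``signal`` is the abundance at ``true_site``; ``background`` bounds
    the off-site abundances (its exact role depends on the category).
    Raises when the requested category is unsatisfiable.
    """
    if not 1 <= true_site <= transcript_length:
        raise ValueError("true_site outside transcript")
    if category not in (0, 1, 2, 3, 4):
        raise ValueError("category must be 0-4")
    rng = np.random.default_rng(seed)
    if transcript_length - 1 < n_background:
        n_background = transcript_length - 1
    candidates = [p for p in range(1, transcript_length + 1) if p != true_site]
    positions = list(rng.choice(candidates, size=n_background, replace=False)) if n_background else []
    profile: dict[int, int] = {}
    if category == 4:
        if signal != 1:
            raise ValueError("category 4 requires exactly one raw read at the site")
        profile = {int(p): int(rng.integers(1, max(2, background + 1))) for p in positions}
    elif category == 0:
        if signal < 2 or background >= signal:
            raise ValueError("category 0 needs signal >= 2 and background < signal")
        profile = {int(p): int(rng.integers(1, background + 1)) if background else 1 for p in positions}
    elif category == 1:
        if signal < 2 or not positions:
            raise ValueError("category 1 needs signal >= 2 and a second peak position")
        profile = {int(p): int(rng.integers(1, min(background, signal - 1) + 1)) for p in positions[1:]}
        profile[int(positions[0])] = signal  # tied maximum
    elif category == 2:
        if background <= signal or signal < 2 or len(positions) < 3:
            raise ValueError("category 2 needs a higher peak and room for low positions")
        profile[int(positions[0])] = background  # the maximum
        for p in positions[1:]:
            profile[int(p)] = 1  # drag the median below the signal
    else:  # category 3
        if signal < 2 or not positions:
            raise ValueError("category 3 needs signal >= 2 and off-site support")
        for p in positions:
            profile[int(p)] = signal + int(rng.integers(0, max(1, background)))
    profile[true_site] = signal
    return profile


@dataclass
class PhasLocusTruth:
    chrom: str
    segment: str
    start: int  # 0-based register origin within the segment
    phased_tags: list[str]
    offphase_tags: list[str]

    @property
    def tags(self) -> list[str]:
        return self.phased_tags + self.offphase_tags


def gen_phas_locus(
    config: SimConfig,
    n_cycles: int = 11,
    n_phased: int = 11,
    n_offphase: int = 0,
    seed: int | None = None,
    chrom: str = "phas1",
    pad: int = 60,
) -> PhasLocusTruth:
    """A genomic segment with 21-nt tags planted on (and off) the register.

    Phased sense tags start exactly on the ``phase``-nt register;
    antisense tags occupy the duplex position two nucleotides behind it
    (their shifted starts land on the register). Off-phase tags start at
    uniformly random off-register positions on either strand.
    """
    phase = config.phase_length
    if n_phased > 2 * n_cycles:
        raise ValueError("n_phased cannot exceed 2 x n_cycles")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    span = phase * n_cycles
    segment = _random_seq(rng, span + 2 * pad)
    start = pad
    slots = [(j, s) for j in range(n_cycles) for s in "+-"]
    chosen = [slots[i] for i in rng.choice(len(slots), size=n_phased, replace=False)]
    phased = []
    for j, strand in sorted(chosen):
        r = start + phase * j
        if strand == "+":
            phased.append(segment[r : r + phase])
        else:
            phased.append(revcomp(segment[r - 2 : r - 2 + phase]))
    offphase = []
    used = set()
    while len(offphase) < n_offphase:
        p = int(rng.integers(start, start + span - phase))
        strand = "+" if rng.random() < 0.5 else "-"
        eff = p if strand == "+" else p + 2
        if (eff - start) % phase == 0 or (eff, strand) in used:
            continue
        used.add((eff, strand))
        seq = segment[p : p + phase]
        offphase.append(seq if strand == "+" else revcomp(seq))
    return PhasLocusTruth(
        chrom=chrom,
        segment=segment,
        start=start,
        phased_tags=phased,
        offphase_tags=offphase,
    )
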