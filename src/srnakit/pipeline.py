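"""End-to-end orchestration: annotate -> identify -> diffexp ->
degradome -> phasing, driven by a single declarative config.

Every threshold defaults to the study value (length 18-28 nt, 2
mismatches / 3 gaps, mature count >= 5, MFE <= -18 kcal/mol, RPM floor
0.01, |M| >= 1 with prob > 0.8, alignment score <= 4.5, phase 21 x 11
cycles, phasing cutoff 1e-4). Re-running with the same config and seed
reproduces byte-identical TSVs.
"""

from __future__ import annotations

import dataclasses
import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from ._seq import revcomp, to_dna
from .annotation import annotate, length_filter, match_genome
from .degradome import DegradomeProfile, call_targets, preprocess_degradome
from .diffexp import de_table, normalize_rpm, run_de
from .io_formats import (
    AnnotationTrack,
    FastaRecord,
    TagTable,
    read_fasta,
    read_tag_table,
    read_tracks_bed,
    write_fasta,
    write_tag_table,
    write_tplot_data,
)
from .mirna import (
    MirbaseEntry,
    align_to_mirbase,
    build_family_representatives,
    predict_novel,
    quantify_known,
)
from .phasing import count_phasirnas, detect_phasirnas, link_triggers
from .synthetic import SimConfig, gen_degradome_profile, gen_phas_locus, simulate


@dataclass
class PipelineConfig:
    # inputs
    genome: str = ""
    tags: str = ""
    mirbase_mature: str = ""
    structural: str = ""
    tracks: str = ""
    cdna: str = ""
    cdna_locations: str = ""
    degradome_tags: str = ""
    groups: dict[str, list[str]] = field(
        default_factory=lambda: {
            "MT": ["MT_bio1", "MT_bio2"],
            "WT": ["WT_bio1", "WT_bio2"],
        }
    )
    # thresholds (study defaults)
    min_length: int = 18
    max_length: int = 28
    max_mismatches: int = 2
    max_gaps: int = 3
    min_count: int = 5
    mfe_max: float = -18.0
    floor: float = 0.01
    m_threshold: float = 1.0
    prob_threshold: float = 0.8
    max_score: float = 4.5
    phase: int = 21
    cycles: int = 11
    phasing_cutoff: float = 1.0e-4
    seed: int = 1

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def validate(self) -> None:
        for key in ("genome", "tags"):
            if not getattr(self, key):
                raise ValueError(f"config is missing required path: {key}")
            if not Path(getattr(self, key)).exists():
                raise ValueError(f"config path does not exist: {key}={getattr(self, key)}")


def _fasta_dict(path: str) -> dict[str, str]:
    return {r.id: r.sequence for r in read_fasta(path)}


def _structural_db(path: str) -> dict[str, str]:
    """Structural-RNA FASTA; source (GenBank/Rfam) read from the description."""
    db = {}
    for rec in read_fasta(path):
        desc = rec.description.lower()
        source = "GenBank" if "genbank" in desc else "Rfam" if "rfam" in desc else "user"
        db[rec.sequence] = source
    return db


def _profiles_from_tags(
    degradome: TagTable, transcripts: dict[str, str]
) -> dict[str, DegradomeProfile]:
    """Map degradome tags to cDNA sense strands; tag 5' ends become the
    per-transcript position -> abundance profile."""
    acc: dict[str, dict[int, int]] = {t: {} for t in transcripts}
    tdna = {t: to_dna(s) for t, s in transcripts.items()}
    for seq in degradome.sequences:
        count = degradome.total(seq)
        q = to_dna(seq)
        for tid, ts in tdna.items():
            pos = ts.find(q)
            while pos != -1:
                acc[tid][pos + 1] = acc[tid].get(pos + 1, 0) + count
                pos = ts.find(q, pos + 1)
    return {
        tid: DegradomeProfile(tid, len(transcripts[tid]), prof)
        for tid, prof in acc.items()
        if prof
    }


def run_all(config: PipelineConfig, out_dir: str | Path, log=print) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        log(f"[{time.strftime('%H:%M:%S')}] stage={name}")

    # --- annotate -----------------------------------------------------
    stage("annotate")
    tags = read_tag_table(config.tags)
    tags, removed = length_filter(tags, config.min_length, config.max_length)
    genome = _fasta_dict(config.genome)
    hits = match_genome(tags, genome)
    tracks = read_tracks_bed(config.tracks) if config.tracks else AnnotationTrack()
    mirna_db_records = read_fasta(config.mirbase_mature) if config.mirbase_mature else []
    mirna_db = [r.sequence for r in mirna_db_records]
    structural = _structural_db(config.structural) if config.structural else {}
    annotated, summary = annotate(tags, tracks, mirna_db, structural, hits)
    summary.to_csv(out / "summary.tsv", sep="\t")
    with open(out / "annotated.tsv", "w") as fh:
        fh.write("#sequence\tcategory\tsource\tn_genome_hits\n")
        for t in annotated:
            fh.write(f"{t.sequence}\t{t.category}\t{t.matched_source}\t{len(t.genome_hits)}\n")
    manifest["stages"]["annotate"] = {"rows": len(annotated), "removed": removed}

    # --- identify -----------------------------------------------------
    stage("identify")
    db = []
    for r in mirna_db_records:
        fam = re.search(r"family=(\S+)", r.description)
        db.append(MirbaseEntry(name=r.id, family=fam.group(1) if fam else r.id,
                               sequence=r.sequence))
    mirna_tags = [t.sequence for t in annotated if t.category == "miRNA"]
    assignments = {
        seq: [a.family for a in align_to_mirbase(seq, db, config.max_mismatches, config.max_gaps)]
        for seq in mirna_tags
    }
    assignments = {s: fams for s, fams in assignments.items() if fams}
    reps = build_family_representatives(assignments, tags)
    known_counts = quantify_known(tags, reps, config.max_mismatches)
    with open(out / "known.tsv", "w") as fh:
        fh.write("#family\tsequence\t" + "\t".join(tags.libraries) + "\n")
        for fam in sorted(reps):
            row = known_counts[fam]
            fh.write(fam + "\t" + reps[fam] + "\t" + "\t".join(str(row[l]) for l in tags.libraries) + "\n")
    candidates = {
        t.sequence: t.genome_hits
        for t in annotated
        if t.genome_hits and t.category in ("unann", "intron", "exon")
    }
    novel = predict_novel(
        tags, genome, candidates,
        min_count=config.min_count, mfe_max=config.mfe_max,
    )
    # a hairpin whose mature or star is already a known miRNA is not novel
    known_seqs = {to_dna(s) for s in mirna_db}
    novel = [
        r for r in novel
        if to_dna(r.mature) not in known_seqs
        and (r.star is None or to_dna(r.star) not in known_seqs)
    ]
    for i, r in enumerate(novel):
        r.name = f"miRN{i + 1:02d}"
    with open(out / "novel.tsv", "w") as fh:
        fh.write("#name\tmature\tstar\tchrom\tstart\tstrand\tarm\tmfe\t"
                 + "\t".join(tags.libraries) + "\n")
        for r in novel:
            fh.write("\t".join(
                [r.name, r.mature, r.star or "NA", r.chrom, str(r.start + 1),
                 r.strand, r.arm, f"{r.mfe:.2f}"]
                + [str(r.counts.get(l, 0)) for l in tags.libraries]) + "\n")
    write_fasta(
        [FastaRecord(r.name, r.name, r.precursor) for r in novel],
        out / "precursors.fasta",
    )
    with open(out / "structures.txt", "w") as fh:
        for r in novel:
            fh.write(f">{r.name}\n{r.precursor}\n{r.structure}\n")
    manifest["stages"]["identify"] = {"rows": len(reps) + len(novel),
                                      "known": len(reps), "novel": len(novel)}

    # --- diffexp ------------------------------------------------------
    stage("diffexp")
    import pandas as pd

    counts = {}
    for fam in sorted(reps):
        counts[fam] = known_counts[fam]
    for r in novel:
        counts[r.name] = r.counts
    count_df = pd.DataFrame.from_dict(counts, orient="index")[tags.libraries].fillna(0)
    rpm = normalize_rpm(count_df, tags.library_totals())
    results = run_de(
        rpm, config.groups,
        floor=config.floor,
        m_threshold=config.m_threshold, prob_threshold=config.prob_threshold,
    )
    de_table(results).to_csv(out / "de.tsv", sep="\t")
    manifest["stages"]["diffexp"] = {
        "rows": len(results),
        "significant": sum(r.significant for r in results),
    }

    # --- degradome ----------------------------------------------------
    stage("degradome")
    targets = []
    if config.cdna and config.degradome_tags:
        transcripts = _fasta_dict(config.cdna)
        deg_tags = read_tag_table(config.degradome_tags)
        survivors, ledger = preprocess_degradome(
            {s: deg_tags.total(s) for s in deg_tags.sequences}, structural
        )
        clean = TagTable(deg_tags.counts.loc[sorted(survivors)])
        profiles = _profiles_from_tags(clean, transcripts)
        mirnas = {fam: reps[fam] for fam in reps}
        mirnas.update({r.name: r.mature for r in novel})
        targets = call_targets(mirnas, transcripts, profiles, config.max_score)
        with open(out / "targets.tsv", "w") as fh:
            fh.write("#miRNA\ttarget\tcategory\tcleavage_position\tp_value\t"
                     "fragment_abundance\talignment_score\n")
            for t in targets:
                fh.write(f"{t.mirna}\t{t.transcript}\t{t.category}\t"
                         f"{t.cleavage_position}\tNA\t{t.fragment_abundance}\t"
                         f"{t.score:.2f}\n")
        tplot_dir = out / "tplots"
        tplot_dir.mkdir(exist_ok=True)
        for t in targets:
            write_tplot_data(
                profiles[t.transcript].abundance, t.cleavage_position,
                tplot_dir / f"{t.mirna}_{t.transcript}.tsv",
                transcript_length=profiles[t.transcript].length,
            )
    manifest["stages"]["degradome"] = {"rows": len(targets)}

    # --- phasing ------------------------------------------------------
    stage("phasing")
    loci = detect_phasirnas(
        tags, genome, phase=config.phase, cycles=config.cycles,
        cutoff=config.phasing_cutoff, genome_hits=hits,
    )
    locations = {}
    if config.cdna_locations:
        with open(config.cdna_locations) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                tid, chrom, start = line.rstrip("\n").split("\t")
                locations[tid] = (chrom, int(start))
    if targets:
        loci = link_triggers(loci, targets, locations or None, phase=config.phase)
    with open(out / "phas.tsv", "w") as fh:
        fh.write("#chrom\tstart\tend\tn\tk\tp_value\tn_phasiRNAs\ttrigger\n")
        for l in loci:
            trig = ";".join(f"{m}@{p}" for m, p, _ in l.triggers) or "NA"
            fh.write(f"{l.chrom}\t{l.start + 1}\t{l.end}\t{l.n}\t{l.k}\t"
                     f"{l.p_value:.3e}\t{count_phasirnas(l)}\t{trig}\n")
    with open(out / "phas.bed", "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\tPHAS\t{l.k}\t+\n")
    manifest["stages"]["phasing"] = {"rows": len(loci)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# demo dataset writer
# ---------------------------------------------------------------------------

def write_demo(config: SimConfig, out_dir: str | Path) -> PipelineConfig:
    """Write a complete synthetic input set plus a matching pipeline config.

    The first third of the miRNA loci are declared "known" (their matures
    are written to the reference miRNA FASTA); PHAS segments are added as
    extra chromosomes; a handful of transcripts carry planted cleavage
    sites with degradome support.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate(config)
    genome = dict(ds.genome)
    rows = {s: {l: int(c) for l, c in ds.tags.counts.loc[s].items()} for s in ds.tags.sequences}
    libs = ds.tags.libraries

    # PHAS segments as extra chromosomes
    for i in range(config.n_phas_loci):
        ph = gen_phas_locus(config, seed=config.seed + 900 + i, chrom=f"phas{i + 1}",
                            n_phased=11, n_offphase=3)
        genome[ph.chrom] = ph.segment
        for seq in ph.tags:
            rows.setdefault(seq, {l: 4 for l in libs})

    # known miRNA reference: first third of the loci
    n_known = max(1, len(ds.loci) // 3)
    known = ds.loci[:n_known]
    write_fasta(
        [
            FastaRecord(f"csi-fam{i + 1:02d}", f"family=fam{i + 1:02d}", t.mature)
            for i, t in enumerate(known)
        ],
        out / "mirbase_mature.fa",
    )

    # structural RNA decoys
    import numpy as np

    rng = np.random.default_rng(config.seed + 777)
    structural = []
    for i, src in enumerate(("GenBank", "Rfam")):
        seq = "".join(rng.choice(list("ACGT"), size=80))
        structural.append(FastaRecord(f"rrna{i + 1}", f"{src} rRNA", seq))
        frag = seq[10:32]
        rows.setdefault(frag, {l: 7 for l in libs})
    write_fasta(structural, out / "structural.fa")

    # transcripts with planted cleavage sites for the last loci
    transcripts, locations, deg_rows = [], [], {}
    targets = ds.loci[n_known : n_known + 4]
    for i, t in enumerate(targets):
        body = "".join(rng.choice(list("ACGT"), size=600))
        site = 301  # cleavage opposite miRNA position 10
        wstart = site - (len(t.mature) - 10)
        window = revcomp(t.mature)
        body = body[: wstart - 1] + window + body[wstart - 1 + len(window):]
        tid = f"t{i + 1:02d}"
        transcripts.append(FastaRecord(tid, "", body))
        locations.append((tid, "", -1))
        profile = gen_degradome_profile(600, site, signal=40, background=8,
                                        category=0, seed=config.seed + i)
        for pos, ab in profile.items():
            frag = body[pos - 1 : pos + 19]
            if len(frag) == 20:
                deg_rows[frag] = deg_rows.get(frag, 0) + ab
    write_fasta(transcripts, out / "cdna.fa")
    with open(out / "degradome.tsv", "w") as fh:
        fh.write("sequence\tpool\n")
        for seq, c in deg_rows.items():
            fh.write(f"{seq}\t{c}\n")

    write_fasta([FastaRecord(c, "", s) for c, s in genome.items()], out / "genome.fa")
    table = TagTable.from_rows(rows.items(), libs)
    write_tag_table(table, out / "tags.tsv")

    pipe = PipelineConfig(
        genome=str(out / "genome.fa"),
        tags=str(out / "tags.tsv"),
        mirbase_mature=str(out / "mirbase_mature.fa"),
        structural=str(out / "structural.fa"),
        cdna=str(out / "cdna.fa"),
        degradome_tags=str(out / "degradome.tsv"),
        seed=config.seed,
    )
    pipe.to_yaml(out / "config.yaml")
    return pipe
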