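"""Synthetic genomes, transcripts, reads and genotype panels with planted truth.

The generator emulates the dual-sequencing design the pipeline expects:
multi-exon genes whose spliced transcripts carry planted biallelic SNPs,
genomic read pairs drawn from the unspliced genome (so that reads crossing
an intron align to transcripts with soft-clipped change points), RNA read
pairs drawn from the spliced transcripts, and two-population genotype
matrices with a controlled F_ST under the Balding-Nichols model.

A single global seed governs all draws.  Draw order is fixed: genome
construction (per gene: exon lengths, intron lengths, bases), SNP planting
(positions, alt alleles, ancestral and per-population frequencies), then
reads (DNA first, RNA second; per fragment: position, allele draws, error
positions), then genotype panels.  Reads carry a constant PHRED quality
(Q30 by default) and a uniform-substitution error model: enough to exercise
the high-quality-base filters without modelling indels or coverage bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from txsnp.io_formats import (
    AlignmentRecord,
    GenotypeMatrix,
    ReadRecord,
    TranscriptRecord,
)

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror a scaled-down two-breed
    validation panel (two populations of 70 individuals, 92 loci, F_ST 0.05)
    and 50x dual sequencing at 0.5% base error."""

    seed: int = 1
    n_genes: int = 20
    exons_per_gene: int = 3
    exon_len_range: tuple[int, int] = (150, 300)
    intron_len_range: tuple[int, int] = (80, 200)
    intergenic_len: int = 150
    snp_rate: float = 0.005
    read_len: int = 100
    fragment_len_range: tuple[int, int] = (250, 400)
    depth_dna: float = 50.0
    depth_rna: float = 50.0
    base_error_rate: float = 0.005
    base_quality: int = 30
    min_aln_len: int = 20
    n_individuals: int = 70
    n_populations: int = 2
    n_loci: int = 92
    target_fst: float = 0.05
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)

    def __post_init__(self) -> None:
        for name in ("n_genes", "exons_per_gene", "read_len",
                     "n_individuals", "n_populations", "n_loci"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("exon_len_range", "intron_len_range",
                     "fragment_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} is inverted: ({lo}, {hi})")
        for name in ("snp_rate", "base_error_rate"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ConfigError(f"{name} must be in [0, 1)")
        if not 0.0 <= self.target_fst < 1.0:
            raise ConfigError("target_fst must be in [0, 1)")


@dataclass(frozen=True)
class PlantedSnp:
    transcript_id: str
    pos: int            # 1-based on transcript
    ref: str
    alt: str
    pop_freqs: tuple[float, ...]   # alt-allele frequency per population

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.transcript_id, self.pos, self.ref, self.alt)


@dataclass
class ExonMap:
    """Exon layout of one gene: genome interval per exon, in transcript order."""
    transcript_id: str
    # (genome_start, genome_end) 1-based closed, one per exon
    exons: list[tuple[int, int]]

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def ieb_positions(self) -> list[int]:
        """Transcript positions of internal exon junctions (last base of each
        non-final exon)."""
        out, cum = [], 0
        for s, e in self.exons[:-1]:
            cum += e - s + 1
            out.append(cum)
        return out


@dataclass
class TruthSet:
    snps: list[PlantedSnp]
    exon_maps: dict[str, ExonMap]
    genotypes: pd.DataFrame | None = None   # dosage of alt allele per ind x locus

    def ieb_positions(self) -> dict[str, list[int]]:
        return {tid: m.ieb_positions() for tid, m in self.exon_maps.items()}

    def snp_keys(self) -> set[tuple[str, int, str, str]]:
        return {s.key for s in self.snps}


@dataclass
class SimulatedReads:
    dna_1: list[ReadRecord]
    dna_2: list[ReadRecord]
    rna_1: list[ReadRecord]
    rna_2: list[ReadRecord]
    g2t_alignments: list[AlignmentRecord]
    t2t_alignments: list[AlignmentRecord]

    @property
    def n_dna_reads(self) -> int:
        return len(self.dna_1) + len(self.dna_2)

    @property
    def n_rna_reads(self) -> int:
        return len(self.rna_1) + len(self.rna_2)


# ---------------------------------------------------------------------------
# genome / transcripts

def simulate_genome_and_transcripts(
    config: SimulationConfig,
) -> tuple[str, list[TranscriptRecord], TruthSet]:
    """Build a genome of multi-exon genes and their spliced transcripts.

    Each transcript is exactly the concatenation of its gene's exons, so the
    truth IEBs are the internal junction positions.  SNPs are planted on
    transcripts at ``snp_rate`` per bp with Balding-Nichols per-population
    alt frequencies around a uniform ancestral frequency.
    """
    rng = np.random.default_rng(config.seed)
    genome_parts: list[str] = []
    transcripts: list[TranscriptRecord] = []
    exon_maps: dict[str, ExonMap] = {}
    gpos = 0
    for g in range(config.n_genes):
        tid = f"TR{g + 1}|c0_g1_i1"
        spacer = _random_seq(rng, config.intergenic_len)
        genome_parts.append(spacer)
        gpos += len(spacer)
        exons: list[tuple[int, int]] = []
        exon_seqs: list[str] = []
        for e in range(config.exons_per_gene):
            elen = int(rng.integers(config.exon_len_range[0],
                                    config.exon_len_range[1] + 1))
            seq = _random_seq(rng, elen)
            exons.append((gpos + 1, gpos + elen))
            exon_seqs.append(seq)
            genome_parts.append(seq)
            gpos += elen
            if e < config.exons_per_gene - 1:
                ilen = int(rng.integers(config.intron_len_range[0],
                                        config.intron_len_range[1] + 1))
                genome_parts.append(_random_seq(rng, ilen).lower())
                gpos += ilen
        transcripts.append(TranscriptRecord(tid, "".join(exon_seqs)))
        exon_maps[tid] = ExonMap(tid, exons)
    genome = "".join(genome_parts).upper()

    snps = _plant_snps(rng, transcripts, config)
    return genome, transcripts, TruthSet(snps=snps, exon_maps=exon_maps)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _plant_snps(rng: np.random.Generator,
                transcripts: Sequence[TranscriptRecord],
                config: SimulationConfig) -> list[PlantedSnp]:
    snps: list[PlantedSnp] = []
    lo, hi = config.ancestral_maf_range
    for t in transcripts:
        n = rng.binomial(len(t), config.snp_rate)
        if n == 0:
            continue
        positions = np.sort(
            rng.choice(np.arange(1, len(t) + 1), size=n, replace=False))
        for pos in positions:
            ref = t.sequence[pos - 1]
            if ref == "N":
                continue
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            p_anc = float(rng.uniform(lo, hi))
            freqs = _balding_nichols(rng, p_anc, config.target_fst,
                                     config.n_populations)
            snps.append(PlantedSnp(t.transcript_id, int(pos), ref, alt, freqs))
    return snps


def _balding_nichols(rng: np.random.Generator, p: float, fst: float,
                     n_pops: int) -> tuple[float, ...]:
    if fst == 0.0:
        return tuple([p] * n_pops)
    a = p * (1 - fst) / fst
    b = (1 - p) * (1 - fst) / fst
    return tuple(float(x) for x in rng.beta(a, b, size=n_pops))


# ---------------------------------------------------------------------------
# reads

def simulate_reads(genome: str,
                   transcripts: Sequence[TranscriptRecord],
                   truth: TruthSet,
                   config: SimulationConfig) -> SimulatedReads:
    """Draw DNA read pairs from the genome and RNA read pairs from transcripts.

    Every planted SNP segregates at dosage 0.5 in the sequenced pool: each
    fragment covering the site carries the alt allele with probability 1/2.
    Alignments to the transcriptome are produced directly from the known
    layout: RNA reads align full-length; a DNA read aligns by its longest
    run inside a single exon, with the intronic/other-exon remainder soft
    clipped (a local-alignment emulation).  DNA reads with no exonic run of
    at least ``min_aln_len`` bases stay unmapped.
    """
    rng = np.random.default_rng(config.seed + 1)
    if config.read_len > len(genome):
        raise ConfigError("read_len exceeds genome length")
    for t in transcripts:
        if config.read_len > len(t):
            raise ConfigError(f"read_len exceeds length of {t.transcript_id}")

    snp_by_transcript: dict[str, list[PlantedSnp]] = {}
    for s in truth.snps:
        snp_by_transcript.setdefault(s.transcript_id, []).append(s)

    # SNP positions on the genome, via the exon maps
    genome_snps: dict[int, tuple[str, str]] = {}
    for s in truth.snps:
        em = truth.exon_maps[s.transcript_id]
        gp = _transcript_to_genome(em, s.pos)
        genome_snps[gp] = (s.ref, s.alt)

    dna_1: list[ReadRecord] = []
    dna_2: list[ReadRecord] = []
    g2t: list[AlignmentRecord] = []
    n_pairs_dna = int(round(config.depth_dna * len(genome)
                            / (2 * config.read_len)))
    exon_index = _build_exon_index(truth, transcripts)
    for i in range(n_pairs_dna):
        frag_len = int(rng.integers(config.fragment_len_range[0],
                                    config.fragment_len_range[1] + 1))
        frag_len = min(frag_len, len(genome))
        start = int(rng.integers(0, len(genome) - frag_len + 1))  # 0-based
        frag = list(genome[start:start + frag_len])
        for off in range(frag_len):
            hit = genome_snps.get(start + off + 1)
            if hit is not None and rng.random() < 0.5:
                frag[off] = hit[1]
        rid = f"dna{i + 1}"
        r1, r2 = _make_pair(rng, rid, frag, config)
        dna_1.append(r1)
        dna_2.append(r2)
        for mate, rec, g0 in ((1, r1, start),
                              (2, r2, start + frag_len - config.read_len)):
            aln = _align_genomic(rec, mate, g0, exon_index, config)
            if aln is not None:
                g2t.append(aln)

    rna_1: list[ReadRecord] = []
    rna_2: list[ReadRecord] = []
    t2t: list[AlignmentRecord] = []
    counter = 0
    for t in transcripts:
        n_pairs = int(round(config.depth_rna * len(t) / (2 * config.read_len)))
        t_snps = snp_by_transcript.get(t.transcript_id, [])
        for _ in range(n_pairs):
            frag_len = int(rng.integers(config.fragment_len_range[0],
                                        config.fragment_len_range[1] + 1))
            frag_len = min(frag_len, len(t))
            start = int(rng.integers(0, len(t) - frag_len + 1))
            frag = list(t.sequence[start:start + frag_len])
            for s in t_snps:
                off = s.pos - 1 - start
                if 0 <= off < frag_len and rng.random() < 0.5:
                    frag[off] = s.alt
            counter += 1
            rid = f"rna{counter}"
            r1, r2 = _make_pair(rng, rid, frag, config)
            rna_1.append(r1)
            rna_2.append(r2)
            t2t.append(_full_length_alignment(r1, 1, t.transcript_id,
                                              start + 1, config))
            t2t.append(_full_length_alignment(
                r2, 2, t.transcript_id,
                start + frag_len - config.read_len + 1, config))

    return SimulatedReads(dna_1, dna_2, rna_1, rna_2, g2t, t2t)


def _make_pair(rng: np.random.Generator, rid: str, frag: list[str],
               config: SimulationConfig) -> tuple[ReadRecord, ReadRecord]:
    # Mate 1 is the fragment head, mate 2 the tail; both stored in reference
    # (forward) orientation, as the SAM convention keeps them after mapping.
    seq1 = _with_errors(rng, frag[:config.read_len], config)
    seq2 = _with_errors(rng, frag[-config.read_len:], config)
    q = (config.base_quality,) * config.read_len
    return (ReadRecord(rid, 1, seq1, q), ReadRecord(rid, 2, seq2, q))


def _with_errors(rng: np.random.Generator, bases: list[str],
                 config: SimulationConfig) -> str:
    if config.base_error_rate == 0.0:
        return "".join(bases)
    out = list(bases)
    n_err = rng.binomial(len(out), config.base_error_rate)
    if n_err:
        for pos in rng.choice(len(out), size=n_err, replace=False):
            out[pos] = str(rng.choice([b for b in "ACGT" if b != out[pos]]))
    return "".join(out)


def _full_length_alignment(read: ReadRecord, mate: int, tid: str, start: int,
                           config: SimulationConfig) -> AlignmentRecord:
    return AlignmentRecord(
        read_id=read.read_id,
        transcript_id=tid,
        start=start,
        aligned_ops=[("match", config.read_len)],
        mapq=42,
        sequence=read.sequence,
        base_qualities=read.qualities,
        mate=mate,
        is_reverse=(mate == 2),
    )


def _build_exon_index(truth: TruthSet,
                      transcripts: Sequence[TranscriptRecord]):
    """List of (genome_start, genome_end, transcript_id, transcript_start)."""
    index = []
    for t in transcripts:
        em = truth.exon_maps[t.transcript_id]
        cum = 0
        for gs, ge in em.exons:
            index.append((gs, ge, t.transcript_id, cum + 1))
            cum += ge - gs + 1
    index.sort()
    return index


def _transcript_to_genome(em: ExonMap, tpos: int) -> int:
    cum = 0
    for gs, ge in em.exons:
        elen = ge - gs + 1
        if tpos <= cum + elen:
            return gs + (tpos - cum - 1)
        cum += elen
    raise ValueError(f"position {tpos} beyond transcript {em.transcript_id}")


def _align_genomic(read: ReadRecord, mate: int, genome_start0: int,
                   exon_index, config: SimulationConfig
                   ) -> AlignmentRecord | None:
    """Local-alignment emulation: align the longest run of the read that
    falls inside a single exon; soft clip the remainder."""
    r_start = genome_start0 + 1          # 1-based genome coords of the read
    r_end = genome_start0 + config.read_len
    best = None   # (run_len, clip_left, t_start)
    for gs, ge, tid, t_start in exon_index:
        if ge < r_start or gs > r_end:
            continue
        lo = max(gs, r_start)
        hi = min(ge, r_end)
        run = hi - lo + 1
        if best is None or run > best[0]:
            clip_left = lo - r_start
            tpos = t_start + (lo - gs)
            best = (run, clip_left, tid, tpos)
    if best is None or best[0] < config.min_aln_len:
        return None
    run, clip_left, tid, tpos = best
    clip_right = config.read_len - clip_left - run
    ops: list[tuple[str, int]] = []
    if clip_left:
        ops.append(("softclip", clip_left))
    ops.append(("match", run))
    if clip_right:
        ops.append(("softclip", clip_right))
    return AlignmentRecord(
        read_id=read.read_id,
        transcript_id=tid,
        start=tpos,
        aligned_ops=ops,
        mapq=42,
        sequence=read.sequence,
        base_qualities=read.qualities,
        mate=mate,
        is_reverse=(mate == 2),
    )


# ---------------------------------------------------------------------------
# genotype panels

def simulate_genotypes(config: SimulationConfig,
                       population_names: Sequence[str] | None = None
                       ) -> tuple[GenotypeMatrix, TruthSet]:
    """Simulate a multi-population genotype panel under Balding-Nichols drift.

    Per locus, an ancestral alt frequency p is drawn uniformly from
    ``ancestral_maf_range``; each population's frequency is drawn from
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``target_fst`` (shared frequencies
    when F = 0), and genotypes are Hardy-Weinberg draws within populations.
    """
    rng = np.random.default_rng(config.seed + 2)
    if population_names is None:
        if config.n_populations == 2:
            population_names = ["Hungarian", "Tabor"]
        else:
            population_names = [f"Pop{i + 1}" for i in range(config.n_populations)]
    if len(population_names) != config.n_populations:
        raise ConfigError("population_names length != n_populations")

    lo, hi = config.ancestral_maf_range
    loci, ref_alt = [], []
    pop_freqs = np.empty((config.n_loci, config.n_populations))
    for j in range(config.n_loci):
        loci.append(f"L{j + 1:03d}")
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        ref_alt.append((str(ref), str(alt)))
        p = float(rng.uniform(lo, hi))
        pop_freqs[j] = _balding_nichols(rng, p, config.target_fst,
                                        config.n_populations)

    ids, pops, gh = [], [], []
    rows = []
    dosages = []
    for k, pop in enumerate(population_names):
        for i in range(config.n_individuals):
            ids.append(f"{pop}_{i + 1:03d}")
            pops.append(pop)
            gh.append(str(rng.choice(["E", "W", "H"], p=[0.25, 0.25, 0.5])))
            alt_copies = rng.binomial(2, pop_freqs[:, k])
            dosages.append(alt_copies)
            row = []
            for j, d in enumerate(alt_copies):
                ref, alt = ref_alt[j]
                call = {0: ref + ref, 1: "".join(sorted(ref + alt)),
                        2: alt + alt}[int(d)]
                row.append(call)
            rows.append(row)

    calls = pd.DataFrame(rows, index=ids, columns=loci)
    matrix = GenotypeMatrix(
        calls=calls,
        populations=pd.Series(pops, index=ids),
        gh_genotypes=pd.Series(gh, index=ids),
    )
    snps = [
        PlantedSnp(loci[j], 1, ref_alt[j][0], ref_alt[j][1],
                   tuple(pop_freqs[j]))
        for j in range(config.n_loci)
    ]
    truth = TruthSet(
        snps=snps,
        exon_maps={},
        genotypes=pd.DataFrame(np.array(dosages), index=ids, columns=loci),
    )
    return matrix, truth
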