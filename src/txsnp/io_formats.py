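"""Readers and writers for the standard formats the pipeline touches.

Transcripts are the reference everywhere: coordinates are 1-based and fully
closed (SAM/VCF convention), and alignments on the reverse strand are stored
post-reverse-complement, as SAM does.  Genotypes are two-character allele
strings ("AG"), missing = "--"; Genepop export maps A,C,G,T -> 01,02,03,04.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file violated its named standard; message carries the position."""


# Trinity-style two-level identifier: TR<g>|c<c>_g<g2>_i<i>
_TRINITY_ID = re.compile(r"^(?P<gene>\S*c\d+_g\d+)_i\d+$")

_DNA_OK = set("ACGTN")

MISSING_CALL = "--"
_GENEPOP_CODE = {"A": "01", "C": "02", "G": "03", "T": "04"}


def gene_id_of(transcript_id: str) -> str:
    """Strip the trailing isoform suffix (``_i<n>``) from a Trinity-dialect id.

    Identifiers not in the dialect are their own gene id.
    """
    m = _TRINITY_ID.match(transcript_id)
    return m.group("gene") if m else transcript_id


@dataclass(frozen=True)
class TranscriptRecord:
    """A contig: unit of SNP discovery, with a two-level (gene, isoform) id."""

    transcript_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for {self.transcript_id!r}")
        bad = set(self.sequence) - _DNA_OK
        if bad:
            raise ValueError(
                f"{self.transcript_id!r}: non-DNA characters {sorted(bad)!r}"
            )

    @property
    def gene_id(self) -> str:
        return gene_id_of(self.transcript_id)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    mate: int
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id!r}: sequence/quality length mismatch"
            )


@dataclass
class AlignmentRecord:
    """One reported alignment of a read to a transcript.

    ``aligned_ops`` is an ordered list of (op, length) with op in
    {"match", "insertion", "deletion", "softclip"}; soft clips occur only at
    the ends.  ``start`` is the 1-based leftmost aligned reference position.
    ``sequence``/``base_qualities`` cover the full query (clips included),
    already reverse-complemented if the alignment was on the reverse strand.
    """

    read_id: str
    transcript_id: str
    start: int
    aligned_ops: list[tuple[str, int]]
    mapq: int
    sequence: str
    base_qualities: tuple[int, ...]
    mate: int = 1
    is_reverse: bool = False
    is_duplicate: bool = False
    is_multimapped: bool = False

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.read_id!r}: start {self.start} < 1")
        interior = [op for op, _ in self.aligned_ops[1:-1]]
        if "softclip" in interior:
            raise ValueError(
                f"{self.read_id!r}: soft clip not at an alignment end"
            )

    @property
    def reference_span(self) -> int:
        """Number of reference positions consumed (matches + deletions)."""
        return sum(n for op, n in self.aligned_ops if op in ("match", "deletion"))

    @property
    def end(self) -> int:
        """1-based rightmost aligned reference position (closed)."""
        return self.start + self.reference_span - 1

    @property
    def leading_clip(self) -> int:
        if self.aligned_ops and self.aligned_ops[0][0] == "softclip":
            return self.aligned_ops[0][1]
        return 0

    @property
    def trailing_clip(self) -> int:
        if len(self.aligned_ops) > 1 and self.aligned_ops[-1][0] == "softclip":
            return self.aligned_ops[-1][1]
        return 0


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a FASTA file into :class:`TranscriptRecord` objects.

    Strict by design: a sequence line before any header, or a header with an
    empty body, raises :class:`FormatError` naming the offending line.
    Sequences are uppercased.
    """
    records: list[TranscriptRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(
                f"{path}: line {header_line}: header {header!r} has no sequence"
            )
        records.append(TranscriptRecord(header, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FormatError(f"{path}: line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: line {lineno}: sequence before any '>' header"
                    )
                chunks.append(line.upper())
    flush()
    if header is None:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.transcript_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read a FASTQ (PHRED+33) file; mate number parsed from ``/1``/``/2``."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        rid, mate = _split_mate(rec.id)
        out.append(
            ReadRecord(
                read_id=rid,
                mate=mate,
                sequence=str(rec.seq).upper(),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return out


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=f"{r.read_id}/{r.mate}",
                        description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def _split_mate(read_id: str) -> tuple[str, int]:
    if read_id.endswith("/1"):
        return read_id[:-2], 1
    if read_id.endswith("/2"):
        return read_id[:-2], 2
    return read_id, 1


def repair_pairs(
    mate1: Sequence[ReadRecord] | str | Path,
    mate2: Sequence[ReadRecord] | str | Path,
) -> tuple[list[ReadRecord], list[ReadRecord], list[ReadRecord]]:
    """Restore paired-end structure after mates were filtered independently.

    Returns ``(paired1, paired2, orphans)``: the paired outputs contain
    exactly the reads whose id occurs in both inputs, in mate-1 input order;
    orphans holds the rest.  A duplicated read id within one input is an
    error.
    """
    r1 = read_fastq(mate1) if isinstance(mate1, (str, Path)) else list(mate1)
    r2 = read_fastq(mate2) if isinstance(mate2, (str, Path)) else list(mate2)
    by_id_2: dict[str, ReadRecord] = {}
    for r in r2:
        if r.read_id in by_id_2:
            raise ValueError(f"duplicate read id {r.read_id!r} in mate-2 input")
        by_id_2[r.read_id] = r
    seen1: set[str] = set()
    paired1: list[ReadRecord] = []
    paired2: list[ReadRecord] = []
    orphans: list[ReadRecord] = []
    for r in r1:
        if r.read_id in seen1:
            raise ValueError(f"duplicate read id {r.read_id!r} in mate-1 input")
        seen1.add(r.read_id)
        if r.read_id in by_id_2:
            paired1.append(r)
            paired2.append(by_id_2[r.read_id])
        else:
            orphans.append(r)
    orphans.extend(r for r in r2 if r.read_id not in seen1)
    return paired1, paired2, orphans


# ---------------------------------------------------------------------------
# SAM

_OP_FROM_CIGAR = {0: "match", 7: "match", 8: "match",
                  1: "insertion", 2: "deletion", 4: "softclip"}
_CIGAR_FROM_OP = {"match": 0, "insertion": 1, "deletion": 2, "softclip": 4}


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read a text SAM file of reads aligned to transcripts.

    The multimapping flag is set on every alignment of a read id that has
    reported alignments to two or more distinct transcripts.
    """
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            ops = []
            for code, length in aln.cigartuples or []:
                op = _OP_FROM_CIGAR.get(code)
                if op is None:
                    raise FormatError(
                        f"{path}: read {aln.query_name!r}: unsupported CIGAR "
                        f"op code {code}"
                    )
                ops.append((op, length))
            quals = aln.query_qualities
            out.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    transcript_id=aln.reference_name,
                    start=aln.reference_start + 1,
                    aligned_ops=ops,
                    mapq=aln.mapping_quality,
                    sequence=(aln.query_sequence or "").upper(),
                    base_qualities=tuple(quals) if quals is not None else (),
                    mate=2 if aln.is_read2 else 1,
                    is_reverse=aln.is_reverse,
                    is_duplicate=aln.is_duplicate,
                )
            )
    _flag_multimapped(out)
    return out


def _flag_multimapped(alignments: list[AlignmentRecord]) -> None:
    # a read is an (id, mate) unit: the two mates of a pair are distinct
    # reads and may legitimately map to different transcripts
    targets: dict[tuple[str, int], set[str]] = {}
    for a in alignments:
        targets.setdefault((a.read_id, a.mate), set()).add(a.transcript_id)
    for a in alignments:
        a.is_multimapped = len(targets[(a.read_id, a.mate)]) >= 2


def write_sam(alignments: Iterable[AlignmentRecord],
              transcripts: Sequence[TranscriptRecord],
              path: str | Path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": t.transcript_id, "LN": len(t)} for t in transcripts],
    }
    tid = {t.transcript_id: i for i, t in enumerate(transcripts)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for a in alignments:
            seg = pysam.AlignedSegment(sam.header)
            seg.query_name = a.read_id
            seg.reference_id = tid[a.transcript_id]
            seg.reference_start = a.start - 1
            seg.mapping_quality = a.mapq
            seg.cigartuples = [(_CIGAR_FROM_OP[op], n) for op, n in a.aligned_ops]
            seg.query_sequence = a.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in a.base_qualities))
            flag = 0x1 if a.mate in (1, 2) else 0
            flag |= 0x40 if a.mate == 1 else 0x80
            if a.is_reverse:
                flag |= 0x10
            if a.is_duplicate:
                flag |= 0x400
            seg.flag = flag
            sam.write(seg)


# ---------------------------------------------------------------------------
# VCF

def write_vcf(variants, transcripts: Sequence[TranscriptRecord],
              path: str | Path) -> None:
    """Write putative SNPs as VCF 4.2 (CHROM = transcript id, 1-based POS)."""
    header = pysam.VariantHeader()
    header.add_line("##source=txsnp")
    for t in transcripts:
        header.contigs.add(t.transcript_id, length=len(t))
    header.info.add("DP", 1, "Integer", "Combined supporting depth")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in variants:
            rec = vcf.new_record(
                contig=v.transcript_id,
                start=v.pos - 1,
                stop=v.pos,
                alleles=(v.ref, v.alt),
            )
            depth = getattr(v, "depth", None)
            if depth is not None:
                rec.info["DP"] = int(depth)
            vcf.write(rec)


def read_vcf(path: str | Path) -> list[tuple[str, int, str, str]]:
    """Read back (transcript_id, pos, ref, alt) tuples from a VCF."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch():
            out.append((rec.chrom, rec.pos, rec.ref, rec.alts[0]))
    return out


# ---------------------------------------------------------------------------
# Genotype matrices

VALID_GH = {"E", "W", "H"}


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci with population and GH-genotype labels.

    ``calls`` is a DataFrame indexed by individual id with one column per
    locus holding two-character allele strings ("AG"); missing = "--".
    """

    calls: pd.DataFrame
    populations: pd.Series
    gh_genotypes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gh_genotypes is None:
            self.gh_genotypes = pd.Series("H", index=self.calls.index)
        if not self.calls.index.equals(self.populations.index):
            raise ValueError("population labels do not match individuals")
        for locus in self.loci:
            col = self.calls[locus]
            alleles = set("".join(c for c in col if c != MISSING_CALL))
            if len(alleles) > 2:
                raise ValueError(
                    f"locus {locus!r} shows {len(alleles)} alleles; "
                    "matrix must be biallelic"
                )

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.index)

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_individuals(self) -> int:
        return len(self.calls.index)

    def locus_alleles(self, locus: str) -> list[str]:
        """Observed alleles at a locus, sorted alphabetically."""
        seen = set("".join(c for c in self.calls[locus] if c != MISSING_CALL))
        return sorted(seen)

    def dosage(self, order: dict[str, str] | None = None) -> np.ndarray:
        """Counts of the reference allele per (individual, locus); -1 missing.

        The reference allele defaults to the alphabetically first observed
        allele at each locus; ``order`` can override per locus.
        """
        n, m = self.calls.shape
        out = np.full((n, m), -1, dtype=np.int8)
        for j, locus in enumerate(self.loci):
            alleles = self.locus_alleles(locus)
            if not alleles:
                continue
            ref = (order or {}).get(locus, alleles[0])
            col = self.calls[locus].to_numpy()
            for i, call in enumerate(col):
                if call == MISSING_CALL:
                    continue
                out[i, j] = (call[0] == ref) + (call[1] == ref)
        return out

    def subset(self, individuals=None, loci=None) -> "GenotypeMatrix":
        calls = self.calls
        if individuals is not None:
            calls = calls.loc[list(individuals)]
        if loci is not None:
            calls = calls[list(loci)]
        return GenotypeMatrix(
            calls=calls,
            populations=self.populations.loc[calls.index],
            gh_genotypes=self.gh_genotypes.loc[calls.index],
        )


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a genotype CSV: individual_id, population, gh_genotype, loci...

    Calls are two-character allele strings over {A,C,G,T}; "--" = missing.
    An unknown code raises an error listing individual and locus.
    """
    df = pd.read_csv(path, dtype=str).fillna(MISSING_CALL)
    required = ["individual_id", "population", "gh_genotype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df = df.set_index("individual_id")
    loci = [c for c in df.columns if c not in ("population", "gh_genotype")]
    calls = df[loci]
    for ind, row in calls.iterrows():
        for locus, call in row.items():
            if call == MISSING_CALL:
                continue
            if len(call) != 2 or any(b not in "ACGT" for b in call):
                raise FormatError(
                    f"{path}: unknown genotype code {call!r} for individual "
                    f"{ind!r} at locus {locus!r}"
                )
    return GenotypeMatrix(
        calls=calls,
        populations=df["population"],
        gh_genotypes=df["gh_genotype"],
    )


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    df = matrix.calls.copy()
    df.insert(0, "gh_genotype", matrix.gh_genotypes)
    df.insert(0, "population", matrix.populations)
    df.to_csv(path, index_label="individual_id")


def write_genepop(matrix: GenotypeMatrix, path: str | Path,
                  title: str = "txsnp export") -> None:
    """Write Genepop format: one ``Pop`` block per population label,
    2-digit allele codes (A,C,G,T -> 01..04, missing 00)."""
    def code(call: str) -> str:
        if call == MISSING_CALL:
            return "0000"
        return _GENEPOP_CODE[call[0]] + _GENEPOP_CODE[call[1]]

    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in matrix.loci:
            fh.write(locus + "\n")
        for pop in dict.fromkeys(matrix.populations):  # stable order
            fh.write("Pop\n")
            idx = matrix.populations[matrix.populations == pop].index
            for ind in idx:
                row = matrix.calls.loc[ind]
                codes = " ".join(code(row[locus]) for locus in matrix.loci)
                fh.write(f"{ind} , {codes}\n")


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read a transcript abundance TSV (transcript_id, est_counts, tpm)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for want in ("transcript_id", "est_counts"):
        if want not in cols:
            raise FormatError(f"{path}: missing column {want!r}")
    df = df.rename(columns={cols[c]: c for c in cols})
    if df["transcript_id"].duplicated().any():
        dup = df.loc[df["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise FormatError(f"{path}: duplicate transcript id {dup!r}")
    if (df["est_counts"] < 0).any():
        raise FormatError(f"{path}: negative est_counts")
    return df
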