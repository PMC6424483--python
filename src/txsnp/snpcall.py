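"""Dual-evidence SNP calling against a transcriptome reference.

Variants are called independently from transcriptome-read (T2T) and
genomic-read (G2T) pileups, each with its own depth window and minimum
count of high-quality (HQ) alternative bases, and only calls present in
both sources with identical (transcript, position, ref, alt) survive as
putative SNPs.  Depth bounds are applied per site: the minimum depth is
8x for T2T and 20x for G2T, the maximum 200x for both, and the minimum
alt support 2 HQ bases (T2T) / 3 HQ bases (G2T).  Bases qualify as HQ at
PHRED >= 20 by default; the threshold is a parameter and is echoed in
summaries.  Only biallelic substitutions are considered: the alternative
allele is the modal non-reference HQ base (ties broken alphabetically)
and indels are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from txsnp.io_formats import AlignmentRecord, TranscriptRecord

DEFAULT_HQ_THRESHOLD = 20

#: (min_depth, max_depth, min_alt_hq) per evidence source
SOURCE_FILTERS = {
    "T2T": (8, 200, 2),
    "G2T": (20, 200, 3),
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass(frozen=True)
class PileupColumn:
    """Per-position base tally after duplicate removal.

    ``depth`` counts all aligned bases; ``hq_counts`` only bases with
    quality >= the caller's HQ threshold, as (A, C, G, T).
    """

    transcript_id: str
    pos: int
    depth: int
    hq_counts: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if sum(self.hq_counts) > self.depth:
            raise ValueError(
                f"{self.transcript_id}:{self.pos}: HQ counts exceed depth"
            )


@dataclass(frozen=True)
class VariantCall:
    transcript_id: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_hq_count: int
    source: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.transcript_id, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PutativeSnp:
    """A variant confirmed by both evidence sources."""

    transcript_id: str
    pos: int
    ref: str
    alt: str
    depth_t2t: int
    depth_g2t: int
    alt_hq_t2t: int
    alt_hq_g2t: int

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.transcript_id, self.pos, self.ref, self.alt)

    @property
    def depth(self) -> int:
        return self.depth_t2t + self.depth_g2t

    @property
    def alt_fraction(self) -> float:
        hq = self.alt_hq_t2t + self.alt_hq_g2t
        return hq / self.depth if self.depth else 0.0


@dataclass
class SnpSummary:
    """Descriptive statistics of a called SNP set against its reference."""

    n_contigs_with_snps: int
    n_contigs_reference: int
    n_snps: int
    assembly_bp: int

    @property
    def pct_transcripts_with_snps(self) -> float:
        if self.n_contigs_reference == 0:
            raise ValueError("empty reference")
        return 100.0 * self.n_contigs_with_snps / self.n_contigs_reference

    @property
    def mutation_rate_snps_per_bp(self) -> float:
        return self.n_snps / self.assembly_bp if self.assembly_bp else 0.0

    @property
    def snps_per_transcript(self) -> float:
        if self.n_contigs_with_snps == 0:
            return 0.0
        return self.n_snps / self.n_contigs_with_snps

    def as_dict(self) -> dict:
        return {
            "n_contigs_with_snps": self.n_contigs_with_snps,
            "n_contigs_reference": self.n_contigs_reference,
            "pct_transcripts_with_snps": self.pct_transcripts_with_snps,
            "n_snps": self.n_snps,
            "assembly_bp": self.assembly_bp,
            "mutation_rate_snps_per_bp": self.mutation_rate_snps_per_bp,
            "snps_per_transcript": self.snps_per_transcript,
        }


def remove_duplicates(alignments: Iterable[AlignmentRecord]
                      ) -> list[AlignmentRecord]:
    """Drop PCR duplicates: among alignments sharing (transcript, start,
    reference span, mate, orientation), keep the highest-mapq one.

    Losers are flagged ``is_duplicate`` in place and excluded from the
    returned list.
    """
    groups: dict[tuple, AlignmentRecord] = {}
    for a in alignments:
        key = (a.transcript_id, a.start, a.reference_span, a.mate,
               a.is_reverse)
        cur = groups.get(key)
        if cur is None:
            groups[key] = a
        elif a.mapq > cur.mapq:
            cur.is_duplicate = True
            groups[key] = a
        else:
            a.is_duplicate = True
    return list(groups.values())


class TranscriptPileup:
    """Depth and per-base HQ tallies over one transcript (dense arrays)."""

    __slots__ = ("transcript_id", "depth", "hq")

    def __init__(self, transcript_id: str, length: int):
        self.transcript_id = transcript_id
        self.depth = np.zeros(length, dtype=np.int32)
        self.hq = np.zeros((4, length), dtype=np.int32)

    def columns(self) -> Iterable[PileupColumn]:
        covered = np.nonzero(self.depth)[0]
        for i in covered:
            yield PileupColumn(
                transcript_id=self.transcript_id,
                pos=int(i) + 1,
                depth=int(self.depth[i]),
                hq_counts=tuple(int(x) for x in self.hq[:, i]),
            )


def pileup(alignments: Iterable[AlignmentRecord],
           transcripts: Sequence[TranscriptRecord],
           hq_threshold: int = DEFAULT_HQ_THRESHOLD
           ) -> dict[str, TranscriptPileup]:
    """Build per-transcript pileups from duplicate-free alignments.

    Soft-clipped bases are never counted; insertions are skipped on the
    query; deletions consume reference positions without contributing
    depth there.
    """
    piles = {t.transcript_id: TranscriptPileup(t.transcript_id, len(t))
             for t in transcripts}
    lengths = {t.transcript_id: len(t) for t in transcripts}
    for a in alignments:
        if a.is_duplicate:
            continue
        pile = piles.get(a.transcript_id)
        if pile is None:
            raise ValueError(
                f"read {a.read_id!r} aligned to unknown transcript "
                f"{a.transcript_id!r}"
            )
        if a.end > lengths[a.transcript_id]:
            raise ValueError(
                f"read {a.read_id!r} extends past the end of "
                f"{a.transcript_id} ({a.end} > {lengths[a.transcript_id]})"
            )
        rpos = a.start - 1   # 0-based reference cursor
        qpos = 0
        for op, n in a.aligned_ops:
            if op == "softclip" or op == "insertion":
                qpos += n
            elif op == "deletion":
                rpos += n
            else:  # match
                for i in range(n):
                    pile.depth[rpos + i] += 1
                    if qpos + i < len(a.base_qualities) and \
                            a.base_qualities[qpos + i] >= hq_threshold:
                        base = a.sequence[qpos + i]
                        bi = _BASE_INDEX.get(base)
                        if bi is not None:
                            pile.hq[bi, rpos + i] += 1
                rpos += n
                qpos += n
    return piles


def call_variants(columns: Iterable[PileupColumn],
                  reference: Mapping[str, str] | Sequence[TranscriptRecord],
                  source: str) -> list[VariantCall]:
    """Apply one evidence source's depth window and HQ alt-count filter.

    Emits at most one biallelic call per position: alt is the modal
    non-reference HQ base, ties broken alphabetically.
    """
    if source not in SOURCE_FILTERS:
        raise ValueError(f"unknown source {source!r}; expected one of "
                         f"{sorted(SOURCE_FILTERS)}")
    min_depth, max_depth, min_alt = SOURCE_FILTERS[source]
    if not isinstance(reference, Mapping):
        reference = {t.transcript_id: t.sequence for t in reference}
    calls = []
    for col in columns:
        if not (min_depth <= col.depth <= max_depth):
            continue
        ref = reference[col.transcript_id][col.pos - 1]
        ri = _BASE_INDEX.get(ref)
        best_base, best_count = None, 0
        for bi, base in enumerate(_BASES):
            if bi == ri:
                continue
            c = col.hq_counts[bi]
            if c > best_count:   # alphabetical tie-break via scan order
                best_base, best_count = base, c
        if best_base is None or best_count < min_alt:
            continue
        calls.append(VariantCall(
            transcript_id=col.transcript_id,
            pos=col.pos,
            ref=ref,
            alt=best_base,
            depth=col.depth,
            alt_hq_count=best_count,
            source=source,
        ))
    return calls


def intersect_calls(t2t_calls: Sequence[VariantCall],
                    g2t_calls: Sequence[VariantCall]) -> list[PutativeSnp]:
    """Keep variants present in both sources with identical
    (transcript, pos, ref, alt); output carries both depths."""
    g2t_by_key = {c.key: c for c in g2t_calls}
    out = []
    for t in t2t_calls:
        g = g2t_by_key.get(t.key)
        if g is None:
            continue
        out.append(PutativeSnp(
            transcript_id=t.transcript_id,
            pos=t.pos,
            ref=t.ref,
            alt=t.alt,
            depth_t2t=t.depth,
            depth_g2t=g.depth,
            alt_hq_t2t=t.alt_hq_count,
            alt_hq_g2t=g.alt_hq_count,
        ))
    return out


def union_calls(t2t_calls: Sequence[VariantCall],
                g2t_calls: Sequence[VariantCall]
                ) -> set[tuple[str, int, str, str]]:
    """The union of the two sources' call keys (reported alongside the
    intersection for descriptive statistics)."""
    return {c.key for c in t2t_calls} | {c.key for c in g2t_calls}


def summarize(calls: Sequence, reference: Sequence[TranscriptRecord]
              ) -> SnpSummary:
    """Descriptive statistics of any call collection with transcript ids."""
    if not reference:
        raise ValueError("empty reference")
    contigs = {c.transcript_id for c in calls}
    return SnpSummary(
        n_contigs_with_snps=len(contigs),
        n_contigs_reference=len(reference),
        n_snps=len(calls),
        assembly_bp=sum(len(t) for t in reference),
    )


def mapping_rate(alignments: Iterable[AlignmentRecord],
                 total_reads: int) -> float:
    """Percentage of sequenced reads with at least one reported alignment.

    A read is an (id, mate) pair, so a fully aligned paired-end run maps
    to 100%.
    """
    if total_reads == 0:
        raise ValueError("total_reads must be positive")
    aligned = {(a.read_id, a.mate) for a in alignments}
    if len(aligned) > total_reads:
        raise ValueError("more aligned reads than total_reads")
    return 100.0 * len(aligned) / total_reads
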