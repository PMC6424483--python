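"""Reduce a raw assembly to the SNP-calling reference.

Three set filters, applied in any order (they commute): keep transcripts
with nonzero expression evidence, with an open reading frame of at least
``min_peptide_aa`` amino acids (a length-only coding filter), and whose
gene produces exactly one isoform.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from txsnp.io_formats import AlignmentRecord, TranscriptRecord

DEFAULT_MIN_PEPTIDE_AA = 100

_FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class OrfCall:
    """The longest ATG-to-stop open reading frame of a transcript.

    ``start``/``end`` are 1-based positions on the forward transcript
    sequence regardless of strand; ``peptide_length`` excludes the stop.
    """

    transcript_id: str
    frame: int
    start: int
    end: int
    peptide_length: int

    def __post_init__(self) -> None:
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError("ORF span not divisible by 3")


def expression_filter(
    records: Sequence[TranscriptRecord],
    abundances: pd.DataFrame | Mapping[str, float],
) -> list[TranscriptRecord]:
    """Keep transcripts with est_counts > 0 (missing from the table = 0)."""
    if isinstance(abundances, pd.DataFrame):
        counts = dict(zip(abundances["transcript_id"], abundances["est_counts"]))
    else:
        counts = dict(abundances)
    kept = [r for r in records if counts.get(r.transcript_id, 0) > 0]
    if records and not kept:
        warnings.warn("expression filter removed every transcript",
                      stacklevel=2)
    return kept


def naive_abundance(records: Sequence[TranscriptRecord],
                    rna_alignments: Iterable[AlignmentRecord]) -> pd.DataFrame:
    """Fallback abundance table: est_counts = aligned RNA reads per transcript.

    Only zero/nonzero matters for the expression filter, so a plain counter
    over primary alignments suffices; TPM is reported on the same counts.
    """
    counts: Counter[str] = Counter()
    seen: set[tuple[str, int]] = set()
    for a in rna_alignments:
        key = (a.read_id, a.mate)
        if key in seen:
            continue
        seen.add(key)
        counts[a.transcript_id] += 1
    rows = []
    lengths = {r.transcript_id: len(r) for r in records}
    rate_sum = sum(counts[t] / lengths[t] for t in lengths if lengths[t]) or 1.0
    for r in records:
        c = counts[r.transcript_id]
        tpm = 1e6 * (c / lengths[r.transcript_id]) / rate_sum
        rows.append({"transcript_id": r.transcript_id,
                     "est_counts": c, "tpm": tpm})
    return pd.DataFrame(rows)


def find_longest_orf(record: TranscriptRecord,
                     min_peptide_aa: int = DEFAULT_MIN_PEPTIDE_AA
                     ) -> OrfCall | None:
    """Scan all six frames for ATG...stop spans; return the longest ORF with
    at least ``min_peptide_aa`` amino acids, else None.

    Ties break by frame order (+1,+2,+3,-1,-2,-3), then leftmost start on
    the scanned strand.
    """
    seq = record.sequence
    rc = str(Seq(seq).reverse_complement())
    best: tuple[int, int, int, int] | None = None  # (pep_len, -frame_rank, ...)
    for rank, frame in enumerate(_FRAMES):
        strand_seq = seq if frame > 0 else rc
        offset = abs(frame) - 1
        for s0, e0 in _orf_spans(strand_seq, offset):
            pep = (e0 - s0 + 1) // 3 - 1   # exclude the stop codon
            if pep < min_peptide_aa:
                continue
            if best is None or pep > best[0] or (
                    pep == best[0] and (rank, s0) < (best[1], best[2])):
                best = (pep, rank, s0, e0)
    if best is None:
        return None
    pep, rank, s0, e0 = best
    frame = _FRAMES[rank]
    if frame > 0:
        start, end = s0 + 1, e0 + 1
    else:
        # map back from the reverse-complement to forward coordinates
        start, end = len(seq) - e0, len(seq) - s0
    return OrfCall(record.transcript_id, frame, start, end, pep)


def _orf_spans(seq: str, offset: int):
    """Yield 0-based (start, end) of ATG..stop spans (stop included) in one
    frame; unterminated ORFs are not called."""
    stops = {"TAA", "TAG", "TGA"}
    i = offset
    start: int | None = None
    while i + 3 <= len(seq):
        codon = seq[i:i + 3]
        if start is None:
            if codon == "ATG":
                start = i
        elif codon in stops:
            yield (start, i + 2)
            start = None
        i += 3


def coding_filter(records: Sequence[TranscriptRecord],
                  min_peptide_aa: int = DEFAULT_MIN_PEPTIDE_AA
                  ) -> list[TranscriptRecord]:
    """Keep transcripts with a qualifying open reading frame."""
    return [r for r in records
            if find_longest_orf(r, min_peptide_aa) is not None]


def isoform_filter(records: Sequence[TranscriptRecord]
                   ) -> list[TranscriptRecord]:
    """Keep exactly the transcripts whose gene id occurs once."""
    per_gene = Counter(r.gene_id for r in records)
    return [r for r in records if per_gene[r.gene_id] == 1]


def survival_fraction_pct(n_in: int, n_out: int) -> float:
    """Percentage of an assembly surviving a filter."""
    if n_in <= 0:
        raise ValueError("n_in must be positive")
    return 100.0 * n_out / n_in


def mean_isoforms_per_gene(n_isoforms: int, n_genes: int) -> float:
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return n_isoforms / n_genes
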