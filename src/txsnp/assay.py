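"""Selection of assay-ready SNPs with IEB-free flanking sequences.

One SNP per contig is chosen for the genotyping panel.  A candidate is
valid only if its flanks of ``flank_len`` bases fit inside the transcript,
contain no predicted intron-exon boundary, and its contig carries no
multimapped reads.  Secondary putative SNPs inside the flanks are masked
to N.  Ranking (deterministic): distance to the nearest predicted IEB
descending, supporting depth descending, |MAF - 0.5| ascending, position
ascending.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from txsnp.io_formats import TranscriptRecord
from txsnp.snpcall import PutativeSnp

DEFAULT_FLANK_LEN = 60

REJECT_REASONS = ("near_ieb", "short_flank", "multimapped_contig", "none")


@dataclass
class AssayCandidate:
    snp: PutativeSnp
    left_flank: str
    right_flank: str
    status: str                 # "selected" | "rejected"
    reject_reason: str          # one of REJECT_REASONS
    ieb_distance: float = math.inf

    @property
    def assay_id(self) -> str:
        return f"{self.snp.transcript_id}:{self.snp.pos}"


def design_assays(snps: Sequence[PutativeSnp],
                  transcripts: Sequence[TranscriptRecord],
                  iebs: Mapping[str, Sequence[int]],
                  clean_ids: Iterable[str],
                  flank_len: int = DEFAULT_FLANK_LEN,
                  n_select: int | None = None) -> list[AssayCandidate]:
    """Pick at most one assayable SNP per transcript, then the global top
    ``n_select`` by the ranking criteria.

    ``iebs`` maps transcript id to predicted boundary positions (1-based).
    Returns every candidate with its status; the selected set is the
    subset with ``status == "selected"``.
    """
    seqs = {t.transcript_id: t.sequence for t in transcripts}
    clean = set(clean_ids)
    snp_positions: dict[str, list[int]] = {}
    for s in snps:
        snp_positions.setdefault(s.transcript_id, []).append(s.pos)

    candidates: list[AssayCandidate] = []
    per_transcript: dict[str, list[AssayCandidate]] = {}
    for s in snps:
        seq = seqs.get(s.transcript_id)
        if seq is None:
            raise ValueError(f"SNP on unknown transcript {s.transcript_id!r}")
        if not (1 <= s.pos <= len(seq)) or seq[s.pos - 1] != s.ref:
            raise ValueError(
                f"SNP {s.transcript_id}:{s.pos} inconsistent with reference")
        t_iebs = iebs.get(s.transcript_id, ())
        dist = min((abs(s.pos - b) for b in t_iebs), default=math.inf)
        left, right = _flanks(seq, s, snp_positions[s.transcript_id],
                              flank_len)
        cand = AssayCandidate(snp=s, left_flank=left, right_flank=right,
                              status="rejected", reject_reason="none",
                              ieb_distance=dist)
        if s.transcript_id not in clean:
            cand.reject_reason = "multimapped_contig"
        elif s.pos - flank_len < 1 or s.pos + flank_len > len(seq):
            cand.reject_reason = "short_flank"
        elif dist <= flank_len:
            cand.reject_reason = "near_ieb"
        else:
            per_transcript.setdefault(s.transcript_id, []).append(cand)
        candidates.append(cand)

    winners = [min(cands, key=_rank_key)
               for cands in per_transcript.values()]
    winners.sort(key=_rank_key)
    if n_select is not None and n_select > len(winners):
        warnings.warn(
            f"requested {n_select} assays but only {len(winners)} valid "
            "candidates are available", stacklevel=2)
    chosen = winners if n_select is None else winners[:n_select]
    for cand in chosen:
        cand.status = "selected"
    return candidates


def _rank_key(c: AssayCandidate):
    maf = min(c.snp.alt_fraction, 1.0 - c.snp.alt_fraction)
    return (-c.ieb_distance, -c.snp.depth, abs(maf - 0.5),
            c.snp.pos, c.snp.transcript_id)


def _flanks(seq: str, snp: PutativeSnp, all_positions: Sequence[int],
            flank_len: int) -> tuple[str, str]:
    lo = max(0, snp.pos - 1 - flank_len)
    left = list(seq[lo:snp.pos - 1])
    right = list(seq[snp.pos:snp.pos + flank_len])
    for p in all_positions:
        if p == snp.pos:
            continue
        if lo + 1 <= p <= snp.pos - 1:
            left[p - lo - 1] = "N"
        elif snp.pos + 1 <= p <= snp.pos + flank_len and p <= len(seq):
            right[p - snp.pos - 1] = "N"
    return "".join(left), "".join(right)


_ASSAY_RE = re.compile(
    r"^(?P<left>[ACGTN]*)\[(?P<ref>[ACGT])/(?P<alt>[ACGT])\]"
    r"(?P<right>[ACGTN]*)$")


def format_assay(candidate: AssayCandidate) -> str:
    """Render a selected candidate as ``left[ref/alt]right``."""
    if candidate.status != "selected":
        raise ValueError(
            f"cannot format rejected candidate {candidate.assay_id} "
            f"({candidate.reject_reason})")
    s = candidate.snp
    return f"{candidate.left_flank}[{s.ref}/{s.alt}]{candidate.right_flank}"


def parse_assay(text: str) -> tuple[int, str, str]:
    """Recover (position of the SNP within the string, ref, alt) from a
    formatted assay record."""
    m = _ASSAY_RE.match(text.strip().upper())
    if m is None:
        raise ValueError(f"not an assay record: {text!r}")
    return (len(m.group("left")) + 1, m.group("ref"), m.group("alt"))
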