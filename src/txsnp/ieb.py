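"""Intron-exon boundary (IEB) prediction on transcripts from change points.

When genomic reads are aligned to a spliced transcript, a read crossing an
exon junction cannot map through its whole length: its alignment starts or
ends internally to the read, leaving a soft-clipped tail.  Such positions
are *change points*.  Against a pooled background rate of spurious clipping,
a position with surprisingly many change points (upper-tail binomial
p-value, Bonferroni-corrected within each transcript) is called an IEB.

Numerical choices: clips shorter than ``min_clip`` (default 5 bp) are
treated as adapter/quality noise; alignments flush with a transcript end
(within ``end_margin`` of either terminus, default the read length) are
expected to clip and are never counted; internal starts and internal ends
are pooled into one count per position (a junction produces both, on
opposite sides); calls within ``merge_window`` (default 5 bp) collapse to
the position with the most change points, ties to the leftmost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binom

from txsnp.io_formats import AlignmentRecord, TranscriptRecord

DEFAULT_MIN_CLIP = 5
DEFAULT_ALPHA = 0.01
DEFAULT_MERGE_WINDOW = 5


@dataclass
class ChangePointProfile:
    """Per-position change-point and coverage tallies for one transcript."""

    transcript_id: str
    internal_starts: np.ndarray
    internal_ends: np.ndarray
    coverage: np.ndarray
    end_margin: int

    @property
    def length(self) -> int:
        return len(self.coverage)

    @property
    def change_points(self) -> np.ndarray:
        return self.internal_starts + self.internal_ends

    def interior(self) -> slice:
        """Positions outside the end margins (0-based slice)."""
        return slice(self.end_margin, max(self.end_margin,
                                          self.length - self.end_margin))


@dataclass(frozen=True)
class IebCall:
    transcript_id: str
    pos: int            # 1-based on transcript
    change_points: int
    coverage: int
    p_value: float


@dataclass
class IebSummary:
    n_iebs: int
    n_transcripts_with_iebs: int

    @property
    def mean_per_transcript(self) -> float:
        if self.n_transcripts_with_iebs == 0:
            return 0.0
        return self.n_iebs / self.n_transcripts_with_iebs


def build_profile(g2t_alignments: Iterable[AlignmentRecord],
                  transcripts: Sequence[TranscriptRecord],
                  min_clip: int = DEFAULT_MIN_CLIP,
                  end_margin: int | None = None
                  ) -> dict[str, ChangePointProfile]:
    """Tally internal alignment starts/ends and coverage per position.

    An alignment contributes an internal start at its first aligned
    position iff its leading soft clip is at least ``min_clip`` bases
    (symmetrically for ends).  ``end_margin`` defaults to the longest read
    length seen.
    """
    alignments = [a for a in g2t_alignments if not a.is_duplicate]
    if end_margin is None:
        end_margin = max((len(a.sequence) for a in alignments), default=0)
    profiles: dict[str, ChangePointProfile] = {}
    lengths = {}
    for t in transcripts:
        L = len(t)
        profiles[t.transcript_id] = ChangePointProfile(
            transcript_id=t.transcript_id,
            internal_starts=np.zeros(L, dtype=np.int32),
            internal_ends=np.zeros(L, dtype=np.int32),
            coverage=np.zeros(L, dtype=np.int32),
            end_margin=end_margin,
        )
        lengths[t.transcript_id] = L
    for a in alignments:
        prof = profiles.get(a.transcript_id)
        if prof is None:
            continue
        L = lengths[a.transcript_id]
        prof.coverage[a.start - 1:a.end] += 1
        if a.leading_clip >= min_clip and a.start > end_margin:
            prof.internal_starts[a.start - 1] += 1
        if a.trailing_clip >= min_clip and a.end <= L - end_margin:
            prof.internal_ends[a.end - 1] += 1
    return profiles


def background_rate(profiles: Iterable[ChangePointProfile]) -> float:
    """Pooled clipping rate: change points per read-touch event, over all
    transcripts, excluding positions within the end margins."""
    cp_total = 0
    touch_total = 0
    for prof in profiles:
        sl = prof.interior()
        cp_total += int(prof.change_points[sl].sum())
        touch_total += int(prof.coverage[sl].sum())
    if touch_total == 0:
        raise ValueError("zero interior coverage; cannot estimate a "
                         "background change-point rate")
    return cp_total / touch_total


def change_point_pvalue(k: int, n: int, p0: float) -> float:
    """Upper-tail binomial probability P[X >= k], X ~ Binomial(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if k == 0:
        return 1.0
    return float(binom.sf(k - 1, n, p0))


def call_iebs(profiles: dict[str, ChangePointProfile],
              alpha: float = DEFAULT_ALPHA,
              merge_window: int = DEFAULT_MERGE_WINDOW,
              p0: float | None = None
              ) -> tuple[list[IebCall], IebSummary]:
    """Call IEBs at Bonferroni-corrected binomial p <= alpha, then merge
    neighbouring calls within ``merge_window`` positions.

    The Bonferroni factor is the number of tested (covered, interior)
    positions of each transcript.  The merged representative is the call
    with the most change points; ties go to the leftmost.
    """
    if p0 is None:
        p0 = background_rate(profiles.values())
    calls: list[IebCall] = []
    transcripts_hit = set()
    for tid, prof in sorted(profiles.items()):
        sl = prof.interior()
        cov = prof.coverage
        cp = prof.change_points
        tested = np.nonzero(cov[sl])[0] + sl.start
        m = len(tested)
        if m == 0:
            continue
        raw: list[IebCall] = []
        for i in tested:
            k = int(cp[i])
            if k == 0:
                continue
            p = change_point_pvalue(k, int(cov[i]), p0)
            if p * m <= alpha:
                raw.append(IebCall(tid, int(i) + 1, k, int(cov[i]),
                                   min(1.0, p * m)))
        merged = _merge(raw, merge_window)
        if merged:
            transcripts_hit.add(tid)
            calls.extend(merged)
    summary = IebSummary(n_iebs=len(calls),
                         n_transcripts_with_iebs=len(transcripts_hit))
    return calls, summary


def _merge(raw: Sequence[IebCall], window: int) -> list[IebCall]:
    if not raw:
        return []
    raw = sorted(raw, key=lambda c: c.pos)
    out: list[IebCall] = []
    cluster = [raw[0]]
    for c in raw[1:]:
        if c.pos - cluster[-1].pos <= window:
            cluster.append(c)
        else:
            out.append(_best(cluster))
            cluster = [c]
    out.append(_best(cluster))
    return out


def _best(cluster: Sequence[IebCall]) -> IebCall:
    return max(cluster, key=lambda c: (c.change_points, -c.pos))


def flag_clean_transcripts(alignments: Iterable[AlignmentRecord],
                           transcript_ids: Iterable[str]) -> set[str]:
    """Transcripts that receive no multimapped alignment (safe for assay
    design)."""
    dirty = {a.transcript_id for a in alignments if a.is_multimapped}
    return {tid for tid in transcript_ids if tid not in dirty}


def iebs_to_bed(calls: Sequence[IebCall]) -> str:
    """Render IEB calls as BED lines (0-based half-open intervals)."""
    lines = []
    for c in sorted(calls, key=lambda c: (c.transcript_id, c.pos)):
        lines.append(f"{c.transcript_id}\t{c.pos - 1}\t{c.pos}\t"
                     f"cp={c.change_points}\t{c.p_value:.3g}")
    return "\n".join(lines) + ("\n" if lines else "")
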