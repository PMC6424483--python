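"""K-mer histogram construction and a peak-based genome-size decomposition.

The estimator is deliberately simple: the haploid length is the total number
of k-mer instances above a noise cutoff divided by the modal (coverage-peak)
multiplicity, and the unique content is the same arithmetic restricted to
the near-single-copy band [peak/2, 2*peak].  A full mixture-model fit of the
histogram is out of scope; the reporting arithmetic, however, is exact.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from txsnp.io_formats import ReadRecord, read_fastq

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class KmerHistogram:
    k: int
    counts: dict[int, int]   # multiplicity -> number of distinct k-mers

    @property
    def total_instances(self) -> int:
        return sum(mult * n for mult, n in self.counts.items())

    @property
    def total_distinct(self) -> int:
        return sum(self.counts.values())


@dataclass
class GenomeSizeReport:
    haploid_length: float
    unique_length: float
    unique_fraction_pct: float
    coverage_peak: int
    noise_cutoff: int

    def as_dict(self) -> dict:
        return {
            "haploid_length": self.haploid_length,
            "unique_length": self.unique_length,
            "unique_fraction_pct": self.unique_fraction_pct,
            "coverage_peak": self.coverage_peak,
            "noise_cutoff": self.noise_cutoff,
        }


def canonical(kmer: str) -> str:
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


def count_kmers(reads: Iterable[ReadRecord] | Iterable[str | Path],
                k: int = 25) -> KmerHistogram:
    """Count canonical k-mers (lexicographic min of k-mer and its reverse
    complement) across reads; k-mers containing N are skipped.

    Accepts FASTQ paths or in-memory reads.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    table: Counter[str] = Counter()
    for item in reads:
        if isinstance(item, (str, Path)):
            for read in read_fastq(item):
                _count_into(table, read.sequence, k)
        else:
            _count_into(table, item.sequence, k)
    hist = Counter(table.values())
    return KmerHistogram(k=k, counts=dict(sorted(hist.items())))


def _count_into(table: Counter, seq: str, k: int) -> None:
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        table[canonical(kmer)] += 1


def estimate_genome_size(hist: KmerHistogram | Mapping[int, int],
                         noise_cutoff: int = 3) -> GenomeSizeReport:
    """Peak-based genome-size decomposition of a k-mer histogram.

    coverage_peak is the modal multiplicity strictly above ``noise_cutoff``
    (multiplicities <= cutoff are treated as sequencing-error k-mers);
    haploid_length = (total instances above cutoff) / peak; unique_length is
    the same ratio restricted to multiplicities in [peak/2, 2*peak].
    """
    counts = hist.counts if isinstance(hist, KmerHistogram) else dict(hist)
    above = {m: n for m, n in counts.items() if m > noise_cutoff}
    if not above:
        raise ValueError(
            f"no k-mer multiplicity above noise cutoff {noise_cutoff}; "
            "cannot locate a coverage peak"
        )
    # modal multiplicity = the one holding the most distinct k-mers
    peak = max(above, key=lambda m: (above[m], -m))
    total = sum(m * n for m, n in above.items())
    haploid = total / peak
    lo, hi = peak / 2, 2 * peak
    unique_instances = sum(m * n for m, n in above.items() if lo <= m <= hi)
    unique = unique_instances / peak
    return GenomeSizeReport(
        haploid_length=haploid,
        unique_length=unique,
        unique_fraction_pct=100.0 * unique / haploid if haploid else 0.0,
        coverage_peak=peak,
        noise_cutoff=noise_cutoff,
    )


def unique_fraction_pct(haploid_length: float, unique_length: float) -> float:
    """The reporting arithmetic alone: 100 * unique / haploid."""
    if haploid_length <= 0:
        raise ValueError("haploid_length must be positive")
    return 100.0 * unique_length / haploid_length
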