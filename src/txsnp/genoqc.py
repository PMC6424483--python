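"""Genotyping panel quality control.

Assayed loci are classified, in order, as *no_signal* (no calls at all),
*disperse* (call rate < 80%), *monomorphic* (MAF < 0.01 among called
individuals), *psv* (paralogous sequence variant: every called individual
heterozygous), or *polymorphic*.  Panel-level rates follow: the conversion
rate excludes only technical failures (no_signal, disperse), while the
validation rate counts only truly polymorphic loci; the two coincide when
no monomorphic or psv loci occur.

The module also assigns growth-hormone (GH) gene phylogroup genotypes from
the lengths of two diagnostic PCR fragments: PS1 (344 bp Western / 341 bp
Eastern) and PS7 (451 bp Western / 455 bp Eastern); hybrids show both
lengths of a fragment.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from txsnp.io_formats import MISSING_CALL, GenotypeMatrix

CATEGORIES = ("no_signal", "disperse", "monomorphic", "psv", "polymorphic")

CALL_RATE_MIN = 0.80
MAF_MIN = 0.01

PS1_LENGTHS = {"W": 344, "E": 341}
PS7_LENGTHS = {"W": 451, "E": 455}


@dataclass
class AssayResult:
    locus_id: str
    n_individuals: int
    n_called: int
    call_rate: float
    maf: float
    category: str


@dataclass
class PanelRates:
    n_assays: int
    n_per_category: dict[str, int]
    conversion_rate_pct: float
    validation_rate_pct: float


def classify_assays(matrix: GenotypeMatrix) -> list[AssayResult]:
    """Classify every locus of a genotype matrix."""
    n = matrix.n_individuals
    if n == 0:
        raise ValueError("genotype matrix has no individuals")
    results = []
    for locus in matrix.loci:
        col = [c for c in matrix.calls[locus] if c != MISSING_CALL]
        n_called = len(col)
        call_rate = n_called / n
        maf = _maf(col)
        if n_called == 0:
            cat = "no_signal"
        elif call_rate < CALL_RATE_MIN:
            cat = "disperse"
        elif maf < MAF_MIN:
            cat = "monomorphic"
        elif all(c[0] != c[1] for c in col):
            cat = "psv"
        else:
            cat = "polymorphic"
        results.append(AssayResult(locus, n, n_called, call_rate, maf, cat))
    return results


def _maf(calls: Sequence[str]) -> float:
    alleles = Counter("".join(calls))
    if len(alleles) < 2:
        return 0.0
    total = sum(alleles.values())
    return min(alleles.values()) / total


def panel_rates(results: Iterable[AssayResult] | Mapping[str, int]
                ) -> PanelRates:
    """Conversion and validation rates of a classified panel (2 d.p.).

    Accepts classified results or a mapping category -> count.
    """
    if isinstance(results, Mapping):
        per_cat = {c: int(results.get(c, 0)) for c in CATEGORIES}
    else:
        per_cat = {c: 0 for c in CATEGORIES}
        for r in results:
            per_cat[r.category] += 1
    n = sum(per_cat.values())
    if n == 0:
        raise ValueError("no assays to rate")
    converted = n - per_cat["no_signal"] - per_cat["disperse"]
    return PanelRates(
        n_assays=n,
        n_per_category=per_cat,
        conversion_rate_pct=round(100.0 * converted / n, 2),
        validation_rate_pct=round(100.0 * per_cat["polymorphic"] / n, 2),
    )


def classify_gh_genotype(ps1_lengths: Iterable[int],
                         ps7_lengths: Iterable[int]) -> str:
    """Assign E (Eastern), W (Western) or H (hybrid) from GH fragment
    lengths.

    W iff only {344} and {451} are seen; E iff only {341} and {455}; any
    fragment showing both lengths means H.  A combination matching neither
    pure pattern (e.g. {341} with {451}) is reported as H with a warning.
    """
    ps1 = set(ps1_lengths)
    ps7 = set(ps7_lengths)
    if not ps1 or not ps7:
        raise ValueError("both fragments need at least one observed length")
    bad1 = ps1 - set(PS1_LENGTHS.values())
    bad7 = ps7 - set(PS7_LENGTHS.values())
    if bad1 or bad7:
        raise ValueError(
            f"inadmissible fragment length(s): PS1 {sorted(bad1)}, "
            f"PS7 {sorted(bad7)}")
    if len(ps1) == 2 or len(ps7) == 2:
        return "H"
    if ps1 == {PS1_LENGTHS["W"]} and ps7 == {PS7_LENGTHS["W"]}:
        return "W"
    if ps1 == {PS1_LENGTHS["E"]} and ps7 == {PS7_LENGTHS["E"]}:
        return "E"
    warnings.warn(
        f"inconsistent single-length combination PS1={sorted(ps1)}, "
        f"PS7={sorted(ps7)}; classifying as hybrid", stacklevel=2)
    return "H"
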