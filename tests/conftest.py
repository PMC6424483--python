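"""Shared fixtures: one simulated sequencing study and one genotype panel,
built once per session so the heavier pipeline stages run a single time."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from txsnp import ieb, popgen, snpcall
from txsnp import simulate as sim


@dataclass
class PipelineRun:
    """A full run of the discovery pipeline on one simulated dataset."""

    config: sim.SimulationConfig
    genome: str
    transcripts: list
    truth: sim.TruthSet
    reads: sim.SimulatedReads
    t2t_dedup: list
    g2t_dedup: list
    t2t_calls: list
    g2t_calls: list
    putative: list
    ieb_profiles: dict
    ieb_calls: list
    ieb_summary: ieb.IebSummary


def run_pipeline(config: sim.SimulationConfig) -> PipelineRun:
    genome, transcripts, truth = sim.simulate_genome_and_transcripts(config)
    reads = sim.simulate_reads(genome, transcripts, truth, config)
    t2t = snpcall.remove_duplicates(reads.t2t_alignments)
    g2t = snpcall.remove_duplicates(reads.g2t_alignments)
    piles_t = snpcall.pileup(t2t, transcripts)
    piles_g = snpcall.pileup(g2t, transcripts)
    t2t_calls = snpcall.call_variants(
        (c for p in piles_t.values() for c in p.columns()), transcripts,
        "T2T")
    g2t_calls = snpcall.call_variants(
        (c for p in piles_g.values() for c in p.columns()), transcripts,
        "G2T")
    putative = snpcall.intersect_calls(t2t_calls, g2t_calls)
    profiles = ieb.build_profile(g2t, transcripts)
    ieb_calls, summary = ieb.call_iebs(profiles)
    return PipelineRun(
        config=config, genome=genome, transcripts=transcripts, truth=truth,
        reads=reads, t2t_dedup=t2t, g2t_dedup=g2t, t2t_calls=t2t_calls,
        g2t_calls=g2t_calls, putative=putative, ieb_profiles=profiles,
        ieb_calls=ieb_calls, ieb_summary=summary,
    )


@pytest.fixture(scope="session")
def pipeline() -> PipelineRun:
    """Default study conditions: 20 three-exon genes, 50x/50x dual
    sequencing, 0.5% base error."""
    return run_pipeline(sim.SimulationConfig(seed=13, n_genes=20))


@pytest.fixture(scope="session")
def panel():
    """Two-breed genotype panel at the validated-array scale
    (2 x 70 individuals, 92 loci, target F_ST 0.05)."""
    cfg = sim.SimulationConfig(seed=17, target_fst=0.05)
    matrix, truth = sim.simulate_genotypes(cfg)
    return matrix, truth


@pytest.fixture(scope="session")
def admixture_fits(panel):
    """Replicate admixture fits for K = 1..4, five runs each."""
    matrix, _ = panel
    return {
        k: [popgen.admixture_em(matrix, k, seed=300 + 10 * k + r)
            for r in range(5)]
        for k in range(1, 5)
    }
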