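"""Shared fixtures: synthetic datasets generated once per session."""

from __future__ import annotations

import pytest

from genome_workbench import mito, synthetic as syn


@pytest.fixture(scope="session")
def element_genome():
    """2 Mb genome with 5 intact / 3 degenerate / 4 solo planted elements."""
    cfg = syn.SimulationConfig(seed=7, element_specs=syn.default_element_panel())
    genome, truth = syn.gen_nuclear_genome(cfg)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def mito_genome():
    """Default 67,195 bp circular mitogenome with three repeat blocks."""
    cfg = syn.SimulationConfig(seed=3)
    rec, truth = syn.gen_mitogenome(cfg)
    return rec, truth


@pytest.fixture(scope="session")
def mito_50x(mito_genome):
    """Error-free 50x long reads plus doubled- and linear-reference alignments."""
    rec, truth = mito_genome
    reads, read_truth = syn.gen_reads(
        rec, syn.ReadSpec(coverage=50, mean_length=8000), seed=3)
    doubled = mito.double_reference(rec)
    alns = mito.align_long_reads(reads, doubled)
    linear = syn.SequenceRecord(rec.id + "_lin", rec.seq, circular=False)
    alns_linear = mito.align_long_reads(reads, linear)
    return dict(ref=rec, reads=reads, read_truth=read_truth,
                alns=alns, alns_linear=alns_linear)
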