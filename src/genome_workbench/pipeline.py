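"""Run configuration and the umbrella pipeline.

All stage thresholds default to the values documented in each module; a
RunConfig rejects unknown keys so typos fail before any stage runs. Every
output file is declared in a JSON manifest with its SHA-256, and all
randomness flows from the single global seed through named substreams, so
identical config + seed reproduces identical manifest hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import expression, hic, io, ltr, mito, synthetic

STAGES = ("simulate", "ltr-scan", "mito", "hic-validate", "tau", "de")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "workbench_out"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    log_level: str = "INFO"
    simulate: dict = field(default_factory=dict)
    ltr_scan: dict = field(default_factory=dict)
    mito: dict = field(default_factory=dict)
    hic_validate: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)

    KNOWN = ("seed", "out_dir", "stages", "log_level", "simulate", "ltr_scan",
             "mito", "hic_validate", "expression")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls.KNOWN)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        bad = set(d.get("stages", [])) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in dependency order; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    seed = config.seed

    sim = synthetic.SimulationConfig(
        seed=seed,
        element_specs=synthetic.default_element_panel(),
        **config.simulate,
    )

    need_sim = set(config.stages) & set(STAGES)
    genome = mito_rec = None
    if need_sim:
        genome, truth_nuc = synthetic.gen_nuclear_genome(sim)
        mito_rec, truth_mt = synthetic.gen_mitogenome(sim)
        io.write_fasta(genome, out / "genome.fasta")
        io.write_fasta([mito_rec], out / "mitogenome.fasta")
        io.write_fasta([synthetic.SequenceRecord("probe", truth_nuc.probe)],
                       out / "probe.fasta")
        io.write_json({"elements": truth_nuc.elements,
                       "mito_blocks": truth_mt.mito_blocks,
                       "coding_region": truth_mt.coding_region},
                      out / "truth.json")
        outputs += [out / "genome.fasta", out / "mitogenome.fasta",
                    out / "probe.fasta", out / "truth.json"]

    if "ltr-scan" in config.stages:
        params = dict(min_identity=85.0, min_length=100)
        params.update(config.ltr_scan)
        hits = ltr.probe_search(genome, truth_nuc.probe, **params)
        cands = ltr.find_flanking_repeat_pairs(genome, hits)
        cons = ltr.build_consensus_ltr(cands, genome)
        ltr_hits = ltr.scan_consensus(genome, cons)
        elements = ltr.classify_elements(ltr_hits, genome,
                                         consensus_length=len(cons.seq))
        io.write_fasta([synthetic.SequenceRecord("consensus_ltr", cons.seq)],
                       out / "consensus_ltr.fasta")
        io.write_gff3(ltr.elements_to_gff3_features(elements), out / "elements.gff3")
        io.write_bed(ltr.elements_to_bed(elements), out / "elements.bed")
        outputs += [out / "consensus_ltr.fasta", out / "elements.gff3",
                    out / "elements.bed"]

    if "mito" in config.stages:
        reads, _ = synthetic.gen_reads(mito_rec, sim.read_spec, seed)
        io.write_fastq(reads, out / "mito_reads.fastq")
        doubled = mito.double_reference(mito_rec)
        alns = mito.align_long_reads(reads, doubled)
        io.write_paf(alns, out / "mito_alignments.paf",
                     {doubled.id: len(doubled)})
        L = len(mito_rec)
        placements = [mito.canonicalize(a, L) for a in alns]
        layout = concat = mito.concatmap_layout(placements,
                                                **config.mito.get("layout", {}))
        layout.to_csv(out / "concatmap_layout.tsv", sep="\t", index=False)
        mito.plot_concatmap(concat, L, str(out / "concatmap.png"))
        cov, anomalies = mito.coverage_and_clipping(alns, L)
        io.write_bed([("mito", a.start, a.end, "anomaly",
                       round(a.fold_enrichment, 2), "+") for a in anomalies],
                     out / "anomalies.bed")
        blocks = mito.decompose_repeat_region(
            mito_rec, (sim.mito_spec.coding_length, L))
        io.write_bed([("mito", b.start, b.end, f"unit_{b.unit_length}",
                       b.copy_number, "+") for b in blocks],
                     out / "repeat_blocks.bed")
        outputs += [out / "mito_reads.fastq", out / "mito_alignments.paf",
                    out / "concatmap_layout.tsv", out / "concatmap.png",
                    out / "anomalies.bed", out / "repeat_blocks.bed"]

    if "hic-validate" in config.stages:
        hspec = synthetic.HiCSpec(**config.hic_validate.get("spec", {}))
        assembly = synthetic.make_hic_assembly(hspec, seed)
        pairs, _ = synthetic.gen_hic_pairs(assembly, hspec, seed)
        io.write_pairs(pairs, out / "contacts.pairs")
        bg = hic.select_background_contigs(assembly, seed=seed,
                                           exclude=(hspec.organelle_id,))
        bg_profiles = [hic.contact_profile(pairs, b) for b in bg]
        qp = hic.contact_profile(pairs, hspec.organelle_id)
        result = hic.classify_contig(qp, bg_profiles)
        hic.profiles_to_long(bg_profiles + [qp]).to_csv(
            out / "hic_profiles.tsv", sep="\t", index=False)
        io.write_json(result.__dict__, out / "hic_classification.json")
        outputs += [out / "contacts.pairs", out / "hic_profiles.tsv",
                    out / "hic_classification.json"]

    if {"tau", "de"} & set(config.stages):
        counts, lengths, meta, _ = synthetic.gen_counts(sim.counts_spec, seed)
        io.write_counts(counts, out / "counts.tsv")
        filt = expression.filter_counts(counts, meta, lengths)
        if "tau" in config.stages:
            tau_tab = expression.assign_specificity(
                expression.tau(expression.cpm(filt), meta))
            tau_tab.to_csv(out / "tau.tsv", sep="\t")
            outputs += [out / "counts.tsv", out / "tau.tsv"]
        if "de" in config.stages:
            for tissue in meta["tissue"].unique():
                de = expression.de_test(filt, meta, tissue)
                de.to_csv(out / f"de_{tissue}.tsv", sep="\t")
                outputs.append(out / f"de_{tissue}.tsv")

    manifest = {
        "seed": seed,
        "stages": list(config.stages),
        "outputs": {p.name: _sha256(p) for p in sorted(set(outputs))},
    }
    io.write_json(manifest, out / "manifest.json")
    return manifest
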