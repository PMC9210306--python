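"""Synthetic data with machine-readable ground truth.

Every pipeline stage in the workbench can be exercised without downloads:
this module plants LTR retroelements in a nuclear genome, builds a circular
mitogenome from a compact coding block plus three tandem-repeat arrays,
samples long/short reads across the circular origin, draws Hi-C contact
pairs with cis enrichment and an unlinked organelle contig, and simulates
negative-binomial count matrices with tissue-specific and
condition-responsive genes.

Defaults mirror the study system the workbench was built around: a ~35% GC
nuclear background, a 67,195 bp mitogenome whose repeat region is three
blocks with unit lengths 125, 1030 and 86 bp around a ~17.5 kb coding
region, a 16-pseudo-chromosome Hi-C assembly, and a three-tissue,
two-condition RNA-seq design.

Coordinates are 0-based half-open on the forward strand. Identical
config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .records import SequenceRecord, revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1")
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


class PlacementError(ValueError):
    """Raised when planted features would overlap or fall off the contig."""


def rng_for(seed: int, label: str) -> np.random.Generator:
    """Named substream: every stage derives its RNG from the one global seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


def random_seq(n: int, rng: np.random.Generator, gc: float = 0.35) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=n, p=p).tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only divergence: each base mutated to a different base."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(arr.size) < rate
    idx = np.flatnonzero(mask)
    for i in idx:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([rng.choice(choices)])
    return arr.tobytes().decode()


def random_orf(length: int, rng: np.random.Generator) -> str:
    """Stop-free reading frame of ``length`` nt (rounded down to codons)."""
    n_codons = length // 3
    return "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons))


def _repair_stops(seq: str, frame_start: int, frame_end: int,
                  rng: np.random.Generator) -> str:
    """Replace stop codons in the frame [frame_start, frame_end) with sense codons."""
    out = list(seq)
    for i in range(frame_start, frame_end - 2, 3):
        if seq[i:i + 3] in STOP_CODONS:
            out[i:i + 3] = rng.choice(SENSE_CODONS)
    return "".join(out)


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

@dataclass
class PlantedElementSpec:
    class_label: str = "intact"  # intact | degenerate | solo
    ltr_length: int = 400
    ltr_pair_divergence: float = 0.02
    internal_length: int = 5000
    orf_length: int = 4500
    insertion_site: tuple[str, int] | None = None  # sampled if None
    truncated_ltr_fraction: float = 0.4  # used for LTR-truncated degenerates

    def __post_init__(self) -> None:
        if self.class_label not in ("intact", "degenerate", "solo"):
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.class_label == "solo":
            self.internal_length = 0
            self.orf_length = 0
        if self.class_label == "intact" and self.orf_length < 3000:
            raise ValueError("intact elements need an ORF >= 3000 nt")


@dataclass
class MitoSpec:
    coding_length: int = 17_500          # compact coding region, ~17.5 kb
    repeat_units: tuple[int, ...] = (125, 1030, 86)
    repeat_copies: tuple[int, ...] = (124, 28, 60)
    spacer_length: int = 65              # three spacers -> total 67,195 bp
    per_copy_divergence: float = 0.01
    gc: float = 0.35


@dataclass
class ReadSpec:
    platform: str = "long"               # long | short
    coverage: float = 50.0
    mean_length: int = 8000
    min_length: int = 500
    read_length: int = 150               # for platform == short
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    both_strands: bool = True


@dataclass
class HiCSpec:
    n_chromosomes: int = 16
    chromosome_length: int = 600_000
    n_pairs: int = 200_000
    cis_fraction: float = 0.8
    decay_alpha: float = 1.0
    min_cis_distance: int = 1000
    organelle_id: str = "mito"
    organelle_length: int = 67_195
    organelle_fraction: float = 0.01     # share of all pairs touching the organelle


@dataclass
class CountsSpec:
    n_genes: int = 2000
    tissues: tuple[str, ...] = ("mantle", "gill", "foot")
    n_conditions: int = 2
    n_replicates: int = 4
    dispersion: float = 0.1
    baseline_log_mean: float = 5.0       # natural-log scale of NB means
    baseline_log_sd: float = 1.2
    tissue_specific_fraction: float = 0.05
    specificity_fold: float = 50.0
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    short_gene_fraction: float = 0.05    # genes shorter than 200 bp
    libsize_jitter: float = 0.3


@dataclass
class SimulationConfig:
    seed: int = 0
    gc_fraction: float = 0.35
    genome_length: int = 2_000_000
    min_separation: int = 20_000
    element_specs: list[PlantedElementSpec] = field(default_factory=list)
    mito_spec: MitoSpec = field(default_factory=MitoSpec)
    read_spec: ReadSpec = field(default_factory=ReadSpec)
    hic_spec: HiCSpec = field(default_factory=HiCSpec)
    counts_spec: CountsSpec = field(default_factory=CountsSpec)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")


def default_element_panel(n_intact: int = 5, n_degenerate: int = 3,
                          n_solo: int = 4) -> list[PlantedElementSpec]:
    """The standard planted-element mix: intact, degenerate and solo copies."""
    panel = [PlantedElementSpec("intact") for _ in range(n_intact)]
    panel += [PlantedElementSpec("degenerate") for _ in range(n_degenerate)]
    panel += [PlantedElementSpec("solo") for _ in range(n_solo)]
    return panel


@dataclass
class GroundTruth:
    """Exact machine-readable truth for every planted feature."""

    elements: list[dict] = field(default_factory=list)
    probe: str = ""
    master_ltr: str = ""
    mito_blocks: list[dict] = field(default_factory=list)
    coding_region: tuple[int, int] | None = None
    reads: list[dict] = field(default_factory=list)
    organelle: str | None = None
    genes: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# Nuclear genome with planted LTR elements
# --------------------------------------------------------------------------

def _build_element(spec: PlantedElementSpec, master_ltr: str, master_internal: str,
                   orf_offset: int, rng: np.random.Generator) -> tuple[str, dict]:
    """Assemble one element's sequence and its within-element feature offsets."""
    ltr_len = len(master_ltr)
    ltr5 = mutate(master_ltr, 0.01, rng)
    info: dict = {"class_label": spec.class_label}

    if spec.class_label == "solo":
        info.update(ltr5=(0, ltr_len), ltr3=None, internal=None, orf=None)
        return ltr5, info

    ltr3 = mutate(ltr5, spec.ltr_pair_divergence, rng)
    internal = master_internal[: spec.internal_length]
    if len(internal) < spec.internal_length:
        internal += random_seq(spec.internal_length - len(internal), rng)

    truncate = False
    if spec.class_label == "intact":
        internal = mutate(internal, 0.01, rng)
        internal = _repair_stops(internal, orf_offset, orf_offset + spec.orf_length, rng)
        orf = (ltr_len + orf_offset, ltr_len + orf_offset + spec.orf_length)
    else:
        # degenerate: either the ORF is disrupted, or one LTR is truncated
        truncate = rng.random() < 0.5
        if truncate:
            internal = mutate(internal, 0.01, rng)
            internal = _repair_stops(internal, orf_offset, orf_offset + max(spec.orf_length, 3003), rng)
            orf = None
            keep = int(ltr_len * spec.truncated_ltr_fraction)
            ltr3 = ltr3[:keep]
        else:
            internal = random_seq(spec.internal_length, rng)  # Gag-Pol lost
            orf = None

    seq = ltr5 + internal + ltr3
    info.update(
        ltr5=(0, ltr_len),
        internal=(ltr_len, ltr_len + len(internal)),
        ltr3=(ltr_len + len(internal), len(seq)),
        orf=orf,
        ltr3_truncated=truncate,
    )
    return seq, info


def gen_nuclear_genome(config: SimulationConfig,
                       contig_id: str = "chr1") -> tuple[list[SequenceRecord], GroundTruth]:
    """Background genome with planted intact/degenerate/solo LTR elements.

    Elements replace equal-length background segments so that recorded
    coordinates are final. Overlapping or too-close insertion sites raise
    PlacementError.
    """
    rng = rng_for(config.seed, "nuclear")
    genome = np.frombuffer(
        random_seq(config.genome_length, rng, config.gc_fraction).encode(), dtype="S1"
    ).copy()

    specs = config.element_specs
    master_ltr = random_seq(400, rng) if not specs else random_seq(specs[0].ltr_length, rng)
    master_internal = random_seq(6000, rng)
    orf_offset = 150  # ORF begins 150 nt into the internal region
    # the probe emulates an internal-region amplicon: a slice of the master ORF
    orf_seed = random_orf(5400, rng)
    master_internal = (master_internal[:orf_offset] + orf_seed +
                       master_internal[orf_offset + len(orf_seed):])
    probe = master_internal[orf_offset + 300: orf_offset + 1500]

    truth = GroundTruth(probe=probe, master_ltr=master_ltr)

    # build element sequences first so placement knows the lengths
    built = [_build_element(s, master_ltr, master_internal, orf_offset, rng)
             for s in specs]

    total = sum(len(seq) for seq, _ in built)
    margin = 5000
    if specs and config.genome_length < total + margin * (len(specs) + 1):
        raise PlacementError("genome too short for the requested elements")

    taken: list[tuple[int, int]] = []
    for spec, (seq, info) in zip(specs, built):
        if spec.insertion_site is not None:
            pos = spec.insertion_site[1]
        else:
            for _ in range(1000):
                pos = int(rng.integers(margin, config.genome_length - margin - len(seq)))
                if all(pos + len(seq) + config.min_separation <= s or
                       e + config.min_separation <= pos for s, e in taken):
                    break
            else:
                raise PlacementError("could not place element without overlap")
        end = pos + len(seq)
        if end > config.genome_length:
            raise PlacementError(f"element at {pos} runs off the contig")
        if any(not (end <= s or e <= pos) for s, e in taken):
            raise PlacementError(f"element at {pos} overlaps a previous insertion")
        taken.append((pos, end))
        genome[pos:end] = np.frombuffer(seq.encode(), dtype="S1")

        rec = {"contig": contig_id, "start": pos, "end": end, "strand": "+"}
        for key in ("class_label", "ltr3_truncated"):
            if key in info:
                rec[key] = info[key]
        for key in ("ltr5", "ltr3", "internal", "orf"):
            span = info.get(key)
            rec[key] = None if span is None else (pos + span[0], pos + span[1])
        truth.elements.append(rec)

    truth.elements.sort(key=lambda r: r["start"])
    record = SequenceRecord(contig_id, genome.tobytes().decode())
    return [record], truth


# --------------------------------------------------------------------------
# Circular mitogenome
# --------------------------------------------------------------------------

def gen_mitogenome(config: SimulationConfig) -> tuple[SequenceRecord, GroundTruth]:
    """Circular mitogenome: compact coding block + three tandem-repeat arrays.

    Layout (clockwise from the origin): coding | spacer | block1 | spacer |
    block2 | spacer | block3. With the default spec the total length is
    67,195 bp.
    """
    spec = config.mito_spec
    if any(u <= 0 for u in spec.repeat_units) or any(c < 0 for c in spec.repeat_copies):
        raise ValueError("repeat unit lengths must be positive and copies non-negative")
    rng = rng_for(config.seed, "mito")
    parts = [random_seq(spec.coding_length, rng, spec.gc)]
    truth = GroundTruth(coding_region=(0, spec.coding_length))
    pos = spec.coding_length
    for unit_len, copies in zip(spec.repeat_units, spec.repeat_copies):
        spacer = random_seq(spec.spacer_length, rng, spec.gc)
        parts.append(spacer)
        pos += len(spacer)
        unit = random_seq(unit_len, rng, spec.gc)
        block = "".join(mutate(unit, spec.per_copy_divergence, rng)
                        for _ in range(copies))
        if copies > 0:
            truth.mito_blocks.append({
                "start": pos, "end": pos + len(block),
                "unit_length": unit_len, "copies": copies, "unit": unit,
            })
        parts.append(block)
        pos += len(block)
    seq = "".join(parts)
    return SequenceRecord("mito", seq, circular=True), truth


# --------------------------------------------------------------------------
# Reads
# --------------------------------------------------------------------------

def _apply_errors(seq: str, spec: ReadSpec, rng: np.random.Generator) -> str:
    if spec.sub_rate == 0 and spec.ins_rate == 0 and spec.del_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n = arr.size
    if spec.sub_rate > 0:
        idx = np.flatnonzero(rng.random(n) < spec.sub_rate)
        shift = rng.integers(1, 4, size=idx.size)
        codes = np.searchsorted(BASES, arr[idx])
        arr[idx] = BASES[(codes + shift) % 4]
    out = arr
    if spec.del_rate > 0:
        out = out[rng.random(out.size) >= spec.del_rate]
    if spec.ins_rate > 0:
        ins_at = np.flatnonzero(rng.random(out.size) < spec.ins_rate)
        ins_base = rng.choice(BASES, size=ins_at.size)
        out = np.insert(out, ins_at, ins_base)
    return out.tobytes().decode()


def gen_reads(ref: SequenceRecord, spec: ReadSpec, seed: int,
              name_prefix: str = "read") -> tuple[list[tuple[str, str]], GroundTruth]:
    """Sample reads from a (possibly circular) reference.

    Circular references sample start positions uniformly on [0, L); reads may
    wrap the origin, and the truth records the wrapped source interval and an
    origin-spanning flag. Errors are independent per-base substitutions and
    indels.
    """
    rng = rng_for(seed, f"reads:{ref.id}:{name_prefix}")
    L = len(ref)
    if spec.platform == "short":
        lengths = np.full(max(1, int(np.ceil(spec.coverage * L / spec.read_length))),
                          spec.read_length)
    else:
        n = max(1, int(np.ceil(spec.coverage * L / spec.mean_length)))
        lengths = rng.gamma(shape=3.0, scale=spec.mean_length / 3.0, size=n)
        lengths = np.clip(lengths.astype(int), spec.min_length, None)
    if lengths.max() > L:
        if not ref.circular:
            lengths = np.clip(lengths, None, L)
        else:
            raise ValueError("read length exceeds circular reference length")

    doubled = ref.seq + ref.seq if ref.circular else ref.seq
    truth = GroundTruth()
    reads: list[tuple[str, str]] = []
    for i, m in enumerate(lengths):
        m = int(m)
        if ref.circular:
            s = int(rng.integers(0, L))
        else:
            s = int(rng.integers(0, L - m + 1))
        raw = doubled[s: s + m]
        strand = "-" if (spec.both_strands and rng.random() < 0.5) else "+"
        if strand == "-":
            raw = revcomp(raw)
        seq = _apply_errors(raw, spec, rng)
        name = f"{name_prefix}{i}"
        reads.append((name, seq))
        truth.reads.append({
            "read": name, "start": s, "end": s + m, "strand": strand,
            "origin_spanning": bool(ref.circular and s + m > L),
        })
    return reads, truth


# --------------------------------------------------------------------------
# Hi-C pairs
# --------------------------------------------------------------------------

def make_hic_assembly(spec: HiCSpec, seed: int) -> list[SequenceRecord]:
    """Pseudo-chromosomes plus the organelle contig (sequences i.i.d. at 35% GC)."""
    rng = rng_for(seed, "hic-assembly")
    recs = [SequenceRecord(f"chr{i + 1}", random_seq(spec.chromosome_length, rng))
            for i in range(spec.n_chromosomes)]
    recs.append(SequenceRecord(spec.organelle_id,
                               random_seq(spec.organelle_length, rng), circular=True))
    return recs


def gen_hic_pairs(assembly: list[SequenceRecord], spec: HiCSpec,
                  seed: int) -> tuple["pd.DataFrame", GroundTruth]:
    """Hi-C contacts: cis pairs with power-law distance decay, uniform trans
    background, and an organelle contig whose partners are drawn uniformly
    over nuclear contigs proportional to length."""
    import pandas as pd

    rng = rng_for(seed, "hic-pairs")
    nuclear = [r for r in assembly if r.id != spec.organelle_id]
    has_org = any(r.id == spec.organelle_id for r in assembly)
    lengths = np.array([len(r) for r in nuclear], dtype=float)
    p_len = lengths / lengths.sum()
    ids = [r.id for r in nuclear]

    n_org = int(round(spec.n_pairs * spec.organelle_fraction)) if has_org else 0
    n_nuc = spec.n_pairs - n_org
    id_arr = np.array(ids)

    is_cis = rng.random(n_nuc) < spec.cis_fraction
    ci = rng.choice(len(ids), size=n_nuc, p=p_len)
    len1 = lengths[ci]
    pos1 = np.floor(rng.random(n_nuc) * len1).astype(np.int64)
    # cis: power-law distance decay with random sign, clipped to the contig
    d = spec.min_cis_distance * (rng.pareto(spec.decay_alpha, size=n_nuc) + 1.0)
    sign = np.where(rng.random(n_nuc) < 0.5, 1.0, -1.0)
    pos2_cis = np.clip(pos1 + (sign * d).astype(np.int64), 0, len1.astype(np.int64) - 1)
    # trans: partner contig proportional to length, excluding the home contig
    cj = rng.choice(len(ids), size=n_nuc, p=p_len)
    if len(ids) > 1:
        for _ in range(64):
            clash = ~is_cis & (cj == ci)
            if not clash.any():
                break
            cj[clash] = rng.choice(len(ids), size=int(clash.sum()), p=p_len)
    pos2_trans = np.floor(rng.random(n_nuc) * lengths[cj]).astype(np.int64)
    chrom2 = np.where(is_cis, id_arr[ci], id_arr[cj])
    pos2 = np.where(is_cis, pos2_cis, pos2_trans)

    oj = rng.choice(len(ids), size=n_org, p=p_len)
    df = pd.DataFrame({
        "readID": [f"pair{i}" for i in range(n_nuc + n_org)],
        "chrom1": np.concatenate([id_arr[ci], np.full(n_org, spec.organelle_id)]),
        "pos1": np.concatenate([
            pos1, rng.integers(0, spec.organelle_length, size=n_org)]),
        "chrom2": np.concatenate([chrom2, id_arr[oj]]),
        "pos2": np.concatenate([
            pos2, np.floor(rng.random(n_org) * lengths[oj]).astype(np.int64)]),
        "strand1": "+", "strand2": "+",
    })
    truth = GroundTruth(organelle=spec.organelle_id if has_org else None)
    return df, truth


# --------------------------------------------------------------------------
# Counts
# --------------------------------------------------------------------------

def gen_counts(spec: CountsSpec, seed: int):
    """NB count matrix with planted tissue-specific and DE genes.

    Returns (counts DataFrame genes x samples, gene_lengths Series,
    sample metadata DataFrame, GroundTruth). DE genes carry the stated
    log2FC between condition groups within every tissue.
    """
    import pandas as pd

    rng = rng_for(seed, "counts")
    G = spec.n_genes
    genes = [f"g{i:05d}" for i in range(G)]
    tissues = list(spec.tissues)
    samples, tissue_of, cond_of = [], [], []
    for t in tissues:
        for c in range(spec.n_conditions):
            for r in range(spec.n_replicates):
                samples.append(f"{t}_c{c + 1}_r{r + 1}")
                tissue_of.append(t)
                cond_of.append(f"c{c + 1}")
    meta = pd.DataFrame({"sample": samples, "tissue": tissue_of,
                         "condition": cond_of}).set_index("sample")

    base = np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=G))

    n_ts = int(round(G * spec.tissue_specific_fraction))
    n_de = int(round(G * spec.de_fraction))
    perm = rng.permutation(G)
    ts_idx = perm[:n_ts]
    de_idx = perm[n_ts:n_ts + n_de]
    ts_tissue = rng.choice(len(tissues), size=n_ts)
    de_sign = rng.choice([-1.0, 1.0], size=n_de)

    mean = np.tile(base[:, None], (1, len(samples)))
    for k, g in enumerate(ts_idx):
        home = tissues[ts_tissue[k]]
        off = np.array([t != home for t in tissue_of])
        mean[g, off] /= spec.specificity_fold
    for k, g in enumerate(de_idx):
        in_c2 = np.array([c != "c1" for c in cond_of])
        mean[g, in_c2] *= 2.0 ** (de_sign[k] * spec.de_log2fc)

    libfac = 1.0 + rng.uniform(-spec.libsize_jitter, spec.libsize_jitter,
                               size=len(samples))
    mean = mean * libfac[None, :]

    if spec.dispersion > 0:
        shape = 1.0 / spec.dispersion
        lam = rng.gamma(shape, mean / shape)
    else:
        lam = mean
    counts = pd.DataFrame(rng.poisson(lam), index=genes, columns=samples)

    n_short = int(round(G * spec.short_gene_fraction))
    lens = np.maximum(200, rng.lognormal(7.2, 0.6, size=G).astype(int))
    short = rng.choice(G, size=n_short, replace=False)
    lens[short] = rng.integers(50, 200, size=n_short)
    gene_lengths = pd.Series(lens, index=genes, name="length")

    truth = GroundTruth()
    ts_set = {int(g): tissues[ts_tissue[k]] for k, g in enumerate(ts_idx)}
    de_set = {int(g): float(de_sign[k] * spec.de_log2fc) for k, g in enumerate(de_idx)}
    for i, g in enumerate(genes):
        truth.genes.append({
            "gene": g,
            "tissue_specific": i in ts_set,
            "specific_tissue": ts_set.get(i),
            "de": i in de_set,
            "true_log2fc": de_set.get(i, 0.0),
            "length": int(lens[i]),
        })
    return counts, gene_lengths, meta, truth
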