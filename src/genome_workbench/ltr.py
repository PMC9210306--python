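"""Discovery and classification of LTR (Steamer-like) retroelements.

The procedure mirrors the field's probe-driven workflow: a degenerate-primer
amplicon probe seeds a genome-wide local search; windows around the hits are
self-compared to find flanking direct-repeat (LTR) pairs; the LTR copies are
aligned into a majority-rule consensus; a second genome-wide scan with the
consensus recovers every copy, including solo LTR scars; finally paired hits
are classified intact / degenerate / solo, where "intact" requires an open
reading frame strictly longer than 3 kb between the paired LTRs.

The external BLAST dependency is replaced by exact k-mer seeding plus edlib
extension, which is adequate at the >=85% identity regime of recent element
families.
"""

from __future__ import annotations

import edlib
import numpy as np

from ._align import KmerIndex, cluster_seeds, kmer_codes, merge_colinear, encode
from .records import ConsensusLTR, LTRElement, ORF, SeedHit, SequenceRecord, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")

# Thresholds the source procedure leaves implicit; all overridable.
DEFAULTS = dict(
    min_identity=85.0,
    min_hit_length=100,
    ltr_len_range=(100, 1500),
    max_span=15_000,
    min_pair_identity=85.0,
    truncation_fraction=0.5,
    orf_min_length=3000,
    window=20_000,
    k=13,
)


# --------------------------------------------------------------------------
# probe / consensus search
# --------------------------------------------------------------------------

def _pair_identity(a: str, b: str) -> float:
    res = edlib.align(a, b, mode="NW")
    span = max(len(a), len(b))
    return 100.0 * (1.0 - res["editDistance"] / span) if span else 0.0


def probe_search(genome: list[SequenceRecord], probe: str | SequenceRecord,
                 min_identity: float = 85.0, min_length: int = 100,
                 k: int = 13) -> list[SeedHit]:
    """All local alignments of ``probe`` against ``genome`` meeting thresholds.

    Both strands are searched; hits are sorted by score (descending).
    Truncated copies are handled by extending only the seed-supported slice
    of the probe, approximating a local alignment.
    """
    pseq = probe.seq if isinstance(probe, SequenceRecord) else probe.upper()
    if len(pseq) < 50:
        raise ValueError("probe must be at least 50 bp")
    if not set(pseq) - {"N"}:
        raise ValueError("degenerate (all-N) probe")

    hits: list[SeedHit] = []
    for contig in genome:
        if len(contig) < k:
            continue
        index = KmerIndex(contig.seq, k=k)
        for strand in "+-":
            q = pseq if strand == "+" else revcomp(pseq)
            qpos, tpos = index.lookup(q)
            clusters = merge_colinear(
                cluster_seeds(qpos, tpos, k, band=150, max_gap=2000, min_seeds=3),
                max_gap=2000, band=300,
            )
            for cl in clusters:
                full = cl.qspan >= 0.8 * len(q)
                ext = _extend(q, contig.seq, cl, full)
                if ext is None:
                    continue
                tstart, tend, dist = ext
                span = tend - tstart
                identity = 100.0 * (1.0 - dist / max(span, 1))
                if span >= min_length and identity >= min_identity:
                    hits.append(SeedHit(contig.id, tstart, tend, strand,
                                        round(identity, 3), float(span - dist)))
    return _dedup_hits(hits)


def _extend(q: str, target: str, cl, full_query: bool,
            pad: int = 150) -> tuple[int, int, int] | None:
    if full_query:
        qs, qe = 0, len(q)
        wpad = pad + cl.qstart + (len(q) - cl.qend)
    else:
        qs, qe = max(0, cl.qstart - 30), min(len(q), cl.qend + 30)
        wpad = pad
    ws = max(0, cl.tstart - (cl.qstart - qs) - wpad)
    we = min(len(target), cl.tend + (qe - cl.qend) + wpad)
    if we <= ws:
        return None
    res = edlib.align(q[qs:qe], target[ws:we], mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc = res["locations"][0]
    return ws + loc[0], ws + loc[1] + 1, res["editDistance"]


def _dedup_hits(hits: list[SeedHit]) -> list[SeedHit]:
    """Keep the best-scoring hit among mutually overlapping ones."""
    kept: list[SeedHit] = []
    for h in sorted(hits, key=lambda x: -x.score):
        clash = False
        for g in kept:
            if g.contig != h.contig:
                continue
            ov = min(g.end, h.end) - max(g.start, h.start)
            if ov > 0.5 * min(len(g), len(h)):
                clash = True
                break
        if not clash:
            kept.append(h)
    return sorted(kept, key=lambda x: -x.score)


def scan_consensus(genome: list[SequenceRecord], consensus: ConsensusLTR | str,
                   min_identity: float = 85.0, min_length: int = 100,
                   k: int = 13) -> list[SeedHit]:
    """Genome-wide scan with the consensus LTR; finds solo and truncated copies."""
    cseq = consensus.seq if isinstance(consensus, ConsensusLTR) else consensus
    if not cseq:
        raise ValueError("empty consensus")
    return probe_search(genome, cseq, min_identity=min_identity,
                        min_length=min_length, k=k)


# --------------------------------------------------------------------------
# flanking repeat (LTR pair) detection
# --------------------------------------------------------------------------

def _extend_pair(w: str, c1: list[int], c2: list[int], max_mismatch_in_10: int = 3) -> None:
    """Grow both repeat copies outward while local identity stays high.

    Mutates the [start, end) lists in place; trims back to the last match so
    boundaries land on matching bases.
    """
    n = len(w)

    def grow(step: int) -> None:
        recent: list[bool] = []
        while True:
            if step < 0:
                i, j = c1[0] - 1, c2[0] - 1
                if i < 0 or j <= c1[1]:
                    break
            else:
                i, j = c1[1], c2[1]
                if j >= n or i >= c2[0]:
                    break
            match = w[i] == w[j]
            recent.append(match)
            if len(recent) > 10:
                recent.pop(0)
            if recent.count(False) > max_mismatch_in_10:
                break
            if step < 0:
                c1[0] -= 1
                c2[0] -= 1
            else:
                c1[1] += 1
                c2[1] += 1

    grow(-1)
    grow(+1)
    # trim boundary mismatch tails
    while c1[1] > c1[0] and w[c1[1] - 1] != w[c2[1] - 1]:
        c1[1] -= 1
        c2[1] -= 1
    while c1[0] < c1[1] and w[c1[0]] != w[c2[0]]:
        c1[0] += 1
        c2[0] += 1


def find_flanking_repeat_pairs(genome: list[SequenceRecord], hits: list[SeedHit],
                               window: int = 20_000,
                               ltr_len_range: tuple[int, int] = (100, 1500),
                               max_span: int = 15_000,
                               min_pair_identity: float = 85.0,
                               k: int = 13) -> list[LTRElement]:
    """Windowed self-comparison around each hit to find direct repeat pairs.

    Operationalizes manual dotplot inspection: shared k-mers at a consistent
    offset d identify two same-strand repeat copies d apart; candidates are
    refined by boundary extension and scored by pair identity.
    """
    if window < max_span:
        raise ValueError("window must be at least max_span")
    contigs = {c.id: c for c in genome}
    candidates: list[LTRElement] = []
    seen_windows: set[tuple[str, int]] = set()
    for hit in hits:
        key = (hit.contig, hit.start // window)
        if key in seen_windows:
            continue
        seen_windows.add(key)
        contig = contigs[hit.contig]
        ws = max(0, hit.start - window)
        we = min(len(contig), hit.end + window)
        w = contig.seq[ws:we]
        for c1s, c1e, c2s, c2e in _self_repeat_pairs(w, k, ltr_len_range, max_span):
            ident = _pair_identity(w[c1s:c1e], w[c2s:c2e])
            len1, len2 = c1e - c1s, c2e - c2s
            if (ident >= min_pair_identity
                    and ltr_len_range[0] <= max(len1, len2) <= ltr_len_range[1]
                    and min(len1, len2) >= 50
                    and c2e - c1s <= max_span):
                candidates.append(LTRElement(
                    contig=hit.contig, strand="+",
                    ltr5_span=(ws + c1s, ws + c1e),
                    ltr3_span=(ws + c2s, ws + c2e),
                    internal_span=(ws + c1e, ws + c2s),
                    ltr_pair_identity=round(ident, 3),
                ))
    return _dedup_candidates(candidates)


def _self_repeat_pairs(w: str, k: int, ltr_len_range, max_span):
    """Yield (c1s, c1e, c2s, c2e) repeat-pair spans from k-mer offset peaks."""
    codes = kmer_codes(encode(w), k)
    order = np.lexsort((np.arange(codes.size), codes))
    sc = codes[order]
    dups = np.flatnonzero((np.diff(sc) == 0) & (sc[:-1] >= 0))
    if dups.size == 0:
        return []
    p1 = np.minimum(order[dups], order[dups + 1])
    p2 = np.maximum(order[dups], order[dups + 1])
    d = p2 - p1
    ok = (d >= ltr_len_range[0]) & (d <= max_span)
    p1, d = p1[ok], d[ok]
    if p1.size == 0:
        return []
    # group by offset (tolerating small indel drift), then into positional runs
    o = np.lexsort((p1, d))
    p1, d = p1[o], d[o]
    out = []
    splits = np.flatnonzero(np.diff(d) > 30) + 1
    for grp in np.split(np.arange(d.size), splits):
        if grp.size < 5:
            continue
        pg = np.sort(p1[grp])
        dg = int(np.median(d[grp]))
        runs = np.split(np.arange(pg.size), np.flatnonzero(np.diff(pg) > 200) + 1)
        for run in runs:
            if run.size < 5:
                continue
            c1 = [int(pg[run].min()), int(pg[run].max()) + k]
            if c1[1] - c1[0] < 0.4 * ltr_len_range[0]:
                continue
            c2 = [c1[0] + dg, c1[1] + dg]
            if c2[1] > len(w):
                continue
            _extend_pair(w, c1, c2)
            if c1[1] - c1[0] >= 50 and c2[0] >= c1[1]:
                out.append((c1[0], c1[1], c2[0], c2[1]))
    return out


def _dedup_candidates(cands: list[LTRElement]) -> list[LTRElement]:
    kept: list[LTRElement] = []
    for c in sorted(cands, key=lambda x: -(x.ltr_pair_identity or 0)):
        dup = False
        for g in kept:
            if g.contig != c.contig:
                continue
            ov = min(g.end, c.end) - max(g.start, c.start)
            if ov > 0.7 * min(g.end - g.start, c.end - c.start):
                dup = True
                break
        if not dup:
            kept.append(c)
    return sorted(kept, key=lambda x: (x.contig, x.start))


# --------------------------------------------------------------------------
# consensus
# --------------------------------------------------------------------------

def build_consensus_ltr(candidates: list[LTRElement],
                        genome: list[SequenceRecord]) -> ConsensusLTR:
    """Star-align member LTR copies to the longest member; majority per column.

    Columns whose majority character is a gap are dropped.
    """
    contigs = {c.id: c for c in genome}
    members: list[str] = []
    for c in candidates:
        for span in (c.ltr5_span, c.ltr3_span):
            if span is not None:
                members.append(contigs[c.contig].seq[span[0]:span[1]])
    if len(members) < 2:
        raise ValueError("need at least 2 LTR copies to build a consensus")
    ref = max(members, key=len)
    L = len(ref)
    counts = np.zeros((5, L), dtype=np.int64)  # A C G T gap
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for m in members:
        res = edlib.align(m, ref, mode="NW", task="path")
        qi = ti = 0
        for length, op in _cigar_ops(res["cigar"]):
            if op in "=X":
                for _ in range(length):
                    counts[base_idx.get(m[qi], 0), ti] += 1
                    qi += 1
                    ti += 1
            elif op == "I":  # insertion relative to ref: no ref column
                qi += length
            elif op == "D":
                counts[4, ti: ti + length] += 1
                ti += length
    best = counts.argmax(axis=0)
    support = counts.sum(axis=0)
    keep = best < 4  # drop gap-majority columns
    seq = "".join("ACGT"[b] for b in best[keep])
    majority = (counts.max(axis=0) / np.maximum(support, 1))[keep]
    return ConsensusLTR(seq=seq, support=len(members),
                        column_majority=[round(float(x), 4) for x in majority])


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


# --------------------------------------------------------------------------
# ORFs
# --------------------------------------------------------------------------

def find_orfs(genome: list[SequenceRecord] | SequenceRecord, span: tuple[int, int],
              strand: str = "+", min_length: int = 3000,
              contig: str | None = None) -> list[ORF]:
    """Maximal stop-to-stop reading frames within ``span`` on ``strand``.

    All three frames of the given strand are scanned with the standard
    genetic code; an ORF here is a stop-free frame segment (no start-codon
    requirement), reported in nucleotides with forward-strand coordinates.
    """
    if isinstance(genome, SequenceRecord):
        rec = genome
    else:
        lookup = {c.id: c for c in genome}
        rec = lookup[contig] if contig else genome[0]
    s, e = span
    if not (0 <= s <= e <= len(rec)):
        raise ValueError(f"span {span} outside contig bounds")
    region = rec.seq[s:e]
    if strand == "-":
        region = revcomp(region)
    n = len(region)
    orfs: list[ORF] = []
    for frame in range(3):
        boundaries = [frame - 3]  # virtual stop before the first codon
        for i in range(frame, n - 2, 3):
            if region[i:i + 3] in STOP_CODONS:
                boundaries.append(i)
        last_codon_start = frame + 3 * ((n - frame) // 3) - 3
        boundaries.append(last_codon_start + 3)
        for prev, nxt in zip(boundaries[:-1], boundaries[1:]):
            seg_start, seg_end = prev + 3, nxt
            if seg_end - seg_start < max(min_length, 3):
                continue
            if strand == "+":
                gs, ge = s + seg_start, s + seg_end
            else:
                gs, ge = s + (n - seg_end), s + (n - seg_start)
            orfs.append(ORF(rec.id, gs, ge, strand, frame))
    return sorted(orfs, key=lambda o: -o.length)


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def classify_elements(ltr_hits: list[SeedHit], genome: list[SequenceRecord],
                      consensus_length: int | None = None,
                      max_span: int = 15_000, orf_min_length: int = 3000,
                      truncation_fraction: float = 0.5) -> list[LTRElement]:
    """Pair consensus-scan LTR hits into elements and label them.

    Intact: a paired element with an internal ORF strictly longer than
    ``orf_min_length`` nt and both LTR copies at least ``truncation_fraction``
    of the consensus length. Degenerate: paired but failing either test.
    Solo: an unpaired LTR scar. Pairing maximizes internal ORF length, then
    minimizes element span.
    """
    contigs = {c.id: c for c in genome}
    if consensus_length is None:
        consensus_length = int(np.median([len(h) for h in ltr_hits])) if ltr_hits else 0

    by_group: dict[tuple[str, str], list[SeedHit]] = {}
    for h in ltr_hits:
        by_group.setdefault((h.contig, h.strand), []).append(h)

    elements: list[LTRElement] = []
    for (cid, strand), hits in by_group.items():
        hits = sorted(hits, key=lambda h: h.start)
        contig = contigs[cid]
        pairs = []
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                a, b = hits[i], hits[j]
                if b.start < a.end:
                    continue
                if b.end - a.start > max_span:
                    break
                orfs = find_orfs(contig, (a.end, b.start), strand, min_length=0)
                orf = orfs[0] if orfs else None
                pairs.append((a, b, orf))
        # greedy matching: prefer qualifying ORFs, then longer ORFs, then tighter spans
        pairs.sort(key=lambda p: (
            -(p[2] is not None and p[2].length > orf_min_length),
            -(p[2].length if p[2] else 0),
            p[1].end - p[0].start,
        ))
        used: set[int] = set()
        for a, b, orf in pairs:
            if id(a) in used or id(b) in used:
                continue
            used.add(id(a))
            used.add(id(b))
            ident = _pair_identity(contig.seq[a.start:a.end], contig.seq[b.start:b.end])
            full_ltrs = (len(a) >= truncation_fraction * consensus_length and
                         len(b) >= truncation_fraction * consensus_length)
            has_orf = orf is not None and orf.length > orf_min_length
            label = "intact" if (has_orf and full_ltrs) else "degenerate"
            elements.append(LTRElement(
                contig=cid, strand=strand,
                ltr5_span=(a.start, a.end), ltr3_span=(b.start, b.end),
                internal_span=(a.end, b.start),
                ltr_pair_identity=round(ident, 3),
                orf_span=(orf.start, orf.end) if orf else None,
                orf_length=orf.length if orf else 0,
                class_label=label,
            ))
        for h in hits:
            if id(h) not in used:
                elements.append(LTRElement(
                    contig=cid, strand=strand,
                    ltr5_span=(h.start, h.end), class_label="solo",
                ))
    return sorted(elements, key=lambda e: (e.contig, e.start))


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------

def elements_to_gff3_features(elements: list[LTRElement]) -> list[dict]:
    feats = []
    for i, e in enumerate(elements):
        eid = f"ltr_element_{i:04d}"
        feats.append(dict(contig=e.contig, type="LTR_retrotransposon",
                          start=e.start, end=e.end, strand=e.strand,
                          attributes={"ID": eid, "class": e.class_label,
                                      "orf_length": e.orf_length}))
        for span in (e.ltr5_span, e.ltr3_span):
            if span:
                feats.append(dict(contig=e.contig, type="long_terminal_repeat",
                                  start=span[0], end=span[1], strand=e.strand,
                                  attributes={"Parent": eid}))
    return feats


def elements_to_bed(elements: list[LTRElement]) -> list[tuple]:
    return [(e.contig, e.start, e.end, f"{e.class_label}_{i}", 0, e.strand)
            for i, e in enumerate(elements)]
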