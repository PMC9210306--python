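"""Circular mitogenome structure validation.

A circular genome has no natural origin: linear mappers split or clip reads
that cross the arbitrary start point. Mapping against a doubled reference
(two head-to-tail copies) lets every read align contiguously; folding the
resulting coordinates modulo the circle length L recovers wrapped placements
and an origin-coverage profile with no systematic dip. The same coordinate
frame exposes collapsed tandem repeats as localized coverage excess plus
read clipping, and the repeat region itself is decomposed into tandem blocks
whose unit lengths are estimated from the k-mer distance spectrum and
refined by autocorrelation.
"""

from __future__ import annotations

import edlib
import numpy as np

from ._align import KmerIndex, cluster_seeds, kmer_codes, merge_colinear, encode
from .records import (AlignmentRecord, CanonicalPlacement, CoverageAnomaly,
                      RepeatBlock, SequenceRecord, VariantSite, revcomp)


class InsufficientDataError(ValueError):
    """Raised when a check has no data, as distinct from a negative result."""


# --------------------------------------------------------------------------
# doubled-reference mapping
# --------------------------------------------------------------------------

def double_reference(ref: SequenceRecord) -> SequenceRecord:
    """Two concatenated copies of a circular reference, as a linear sequence.

    The output is flagged linear, so doubling a doubled sequence is rejected.
    """
    if not ref.circular:
        raise ValueError(f"reference {ref.id!r} is not circular")
    return SequenceRecord(ref.id + "_x2", ref.seq * 2, circular=False)


def align_long_reads(reads: list[tuple[str, str]], ref: SequenceRecord,
                     k: int = 15, step: int = 3, band: int = 500,
                     max_gap: int = 1500, min_seeds: int = 4,
                     tail_tolerance: int = 50) -> list[AlignmentRecord]:
    """Seed-chain-extend mapping of reads; at most one primary alignment each.

    The best seed chain (most seeds; ties to the smaller target start) is
    extended with edlib. Query tails longer than ``tail_tolerance`` that the
    chain does not support are reported as clips. Alternatively, PAF from an
    external mapper can be ingested via io.read_paf and used with the same
    downstream operations.
    """
    if not reads:
        raise ValueError("no reads supplied")
    index = KmerIndex(ref.seq, k=k, max_hits_per_kmer=200)
    out: list[AlignmentRecord] = []
    for name, seq in reads:
        best = None
        for strand in "+-":
            q = seq if strand == "+" else revcomp(seq)
            qpos, tpos = index.lookup(q, step=step)
            clusters = merge_colinear(
                cluster_seeds(qpos, tpos, k, band=band, max_gap=max_gap,
                              min_seeds=min_seeds),
                max_gap=max_gap, band=band,
            )
            for cl in clusters:
                # primary selection: query coverage, then seed support, then
                # the smaller canonical start (copy-1 placement on ties)
                key = (cl.qspan, cl.n_seeds, -cl.tstart)
                if best is None or key > best[0]:
                    best = (key, cl, strand, q)
        if best is None:
            continue
        _, cl, strand, q = best
        qs = 0 if cl.qstart <= tail_tolerance else cl.qstart
        qe = len(q) if len(q) - cl.qend <= tail_tolerance else cl.qend
        pad = 100 + (cl.qstart - qs) + (qe - cl.qend)
        ws = max(0, cl.tstart - (cl.qstart - qs) - pad)
        we = min(len(ref), cl.tend + (qe - cl.qend) + pad)
        res = edlib.align(q[qs:qe], ref.seq[ws:we], mode="HW", task="locations")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        loc = res["locations"][0]
        tstart, tend = ws + loc[0], ws + loc[1] + 1
        block = max(qe - qs, tend - tstart)
        clip_left_q, clip_right_q = qs, len(q) - qe
        if strand == "+":
            q_start, q_end = qs, qe
            cl_l, cl_r = clip_left_q, clip_right_q
        else:
            q_start, q_end = len(q) - qe, len(q) - qs
            cl_l, cl_r = clip_right_q, clip_left_q
        out.append(AlignmentRecord(
            query=name, query_length=len(seq), query_start=q_start,
            query_end=q_end, target=ref.id, target_start=tstart,
            target_end=tend, strand=strand,
            matches=max(0, block - res["editDistance"]), block_length=block,
            clip_left=cl_l, clip_right=cl_r, query_seq=seq,
        ))
    return out


def canonicalize(aln: AlignmentRecord, L: int) -> CanonicalPlacement:
    """Fold a doubled-reference alignment onto circular coordinates [0, L)."""
    span = aln.target_end - aln.target_start
    if span > L:
        raise ValueError("aligned span exceeds circle length; not canonicalizable")
    start = aln.target_start % L
    if start + span <= L:
        intervals = [(start, start + span)]
        spanning = False
    else:
        intervals = [(start, L), (0, start + span - L)]
        spanning = True
    return CanonicalPlacement(read=aln.query, read_length=aln.query_length,
                              intervals=intervals, origin_spanning=spanning,
                              strand=aln.strand)


# --------------------------------------------------------------------------
# layout (ConcatMap-style) and coverage
# --------------------------------------------------------------------------

def concatmap_layout(placements: list[CanonicalPlacement],
                     min_read_length: int = 25_000):
    """Plot-ready read layout: one row per read, ordered by canonical start.

    Default length filter is 25 kb, matching the long-read support plot the
    doubled-reference approach was designed for. Wrapped reads contribute two
    segments.
    """
    import pandas as pd

    rows = []
    kept = [p for p in placements if p.read_length >= min_read_length]
    kept.sort(key=lambda p: (p.start, p.read))
    for row, p in enumerate(kept):
        for si, (s, e) in enumerate(p.intervals):
            rows.append(dict(read=p.read, row=row, seg_start=s, seg_end=e,
                             segment=si, origin_spanning=p.origin_spanning,
                             strand=p.strand))
    return pd.DataFrame(rows, columns=["read", "row", "seg_start", "seg_end",
                                       "segment", "origin_spanning", "strand"])


def plot_concatmap(layout, L: int, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 6))
    for _, seg in layout.iterrows():
        color = "tab:red" if seg.origin_spanning else "tab:grey"
        ax.hlines(seg.row, seg.seg_start, seg.seg_end, colors=color, lw=1.5)
    ax.set_xlim(0, L)
    ax.set_xlabel("circular position (bp)")
    ax.set_ylabel("read")
    ax.set_title("doubled-reference read layout")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def coverage_from_placements(placements: list[CanonicalPlacement],
                             L: int) -> np.ndarray:
    cov = np.zeros(L + 1, dtype=np.int64)
    for p in placements:
        for s, e in p.intervals:
            cov[s] += 1
            cov[e] -= 1
    return np.cumsum(cov[:-1])


def coverage_and_clipping(alignments: list[AlignmentRecord], L: int,
                          fold_threshold: float = 3.0,
                          clip_threshold: float = 0.5, window: int = 100,
                          min_clip: int = 20
                          ) -> tuple[np.ndarray, list[CoverageAnomaly]]:
    """Canonical coverage plus collapsed-repeat anomaly calls.

    Anomalies are maximal runs of windows where coverage exceeds
    ``fold_threshold`` times the genome-wide median AND the fraction of
    overlapping reads with a clip boundary in the window exceeds
    ``clip_threshold``.
    """
    placements = [canonicalize(a, L) for a in alignments]
    cov = coverage_from_placements(placements, L)
    if not placements:
        return cov, []
    nwin = (L + window - 1) // window
    overlap = np.zeros(nwin + 1, dtype=np.int64)
    clipped = np.zeros(nwin + 1, dtype=np.int64)
    for aln, p in zip(alignments, placements):
        is_clipped = max(aln.clip_left, aln.clip_right) >= min_clip
        if p.origin_spanning:
            ranges = [(0, nwin)]
        else:
            ranges = [(min(s // window for s, _ in p.intervals),
                       max((e - 1) // window for _, e in p.intervals) + 1)]
        for lo, hi in ranges:
            overlap[lo] += 1
            overlap[hi] -= 1
            if is_clipped:
                clipped[lo] += 1
                clipped[hi] -= 1
    overlap = np.cumsum(overlap[:-1])
    clip_reads = np.cumsum(clipped[:-1])
    med = float(np.median(cov))
    if med == 0:
        return cov, []
    win_cov = np.array([cov[i * window: (i + 1) * window].mean() for i in range(nwin)])
    clip_frac = clip_reads / np.maximum(overlap, 1)
    flagged = (win_cov > fold_threshold * med) & (clip_frac > clip_threshold)
    anomalies: list[CoverageAnomaly] = []
    i = 0
    while i < nwin:
        if flagged[i]:
            j = i
            while j + 1 < nwin and flagged[j + 1]:
                j += 1
            s, e = i * window, min(L, (j + 1) * window)
            anomalies.append(CoverageAnomaly(
                start=s, end=e,
                fold_enrichment=float(win_cov[i:j + 1].mean() / med),
                clipped_fraction=float(clip_frac[i:j + 1].mean()),
            ))
            i = j + 1
        else:
            i += 1
    return cov, anomalies


# --------------------------------------------------------------------------
# tandem repeat decomposition
# --------------------------------------------------------------------------

def _match_track(seq_codes: np.ndarray, lag: int) -> float:
    a = seq_codes[:-lag] if lag else seq_codes
    b = seq_codes[lag:]
    if a.size == 0:
        return 0.0
    return float(np.mean(a == b))


def decompose_repeat_region(ref: SequenceRecord, region: tuple[int, int],
                            k: int = 12, max_unit: int = 2000,
                            min_copies: float = 2.0,
                            min_match: float = 0.6) -> list[RepeatBlock]:
    """Segment a region into maximal tandem arrays and estimate unit lengths.

    Per-position candidate periods come from the distance between successive
    occurrences of shared k-mers; dense runs of consistent period define
    arrays; each array's unit is refined by base-level autocorrelation,
    choosing the smallest lag whose match fraction reaches 95% of the
    maximum (resolving harmonic ambiguity, e.g. 250 vs 125).
    """
    s0, e0 = region
    if not (0 <= s0 < e0 <= len(ref)):
        raise ValueError("region outside reference")
    seq = ref.seq[s0:e0]
    n = len(seq)
    codes = kmer_codes(encode(seq), k)
    if codes.size == 0:
        return []
    order = np.lexsort((np.arange(codes.size), codes))
    sc = codes[order]
    period = np.zeros(codes.size, dtype=np.int64)
    same = (np.diff(sc) == 0) & (sc[:-1] >= 0)
    idx = np.flatnonzero(same)
    p_from = order[idx]
    p_to = order[idx + 1]
    lo = np.minimum(p_from, p_to)
    d = np.abs(p_to - p_from)
    ok = (d >= 10) & (d <= max_unit)
    # keep the smallest distance per position
    for pos, dist in zip(lo[ok], d[ok]):
        if period[pos] == 0 or dist < period[pos]:
            period[pos] = dist

    segments = _segment_periods(period, max_unit)
    enc = encode(seq)
    blocks: list[RepeatBlock] = []
    for seg_s, seg_e, u0 in segments:
        seg_s, seg_e = _refine_boundaries(enc, seg_s, seg_e, u0, min_match)
        if seg_e - seg_s < min_copies * u0:
            continue
        unit = _refine_unit(enc[seg_s:seg_e], u0, max_unit)
        if unit is None or seg_e - seg_s < min_copies * unit:
            continue
        consensus = _unit_consensus(seq[seg_s:seg_e], unit)
        blocks.append(RepeatBlock(
            start=s0 + seg_s, end=s0 + seg_e, unit_length=unit,
            copy_number=round((seg_e - seg_s) / unit, 2),
            unit_consensus=consensus,
        ))
    return _merge_blocks(blocks)


def _merge_blocks(blocks: list[RepeatBlock]) -> list[RepeatBlock]:
    """Collapse near-duplicate arrays found from overlapping period runs."""
    out: list[RepeatBlock] = []
    for b in sorted(blocks, key=lambda x: (x.start, -(x.end - x.start))):
        if out:
            p = out[-1]
            ov = min(p.end, b.end) - max(p.start, b.start)
            same_unit = abs(p.unit_length - b.unit_length) <= max(
                3, 0.05 * min(p.unit_length, b.unit_length))
            if ov > 0.5 * min(p.end - p.start, b.end - b.start) and same_unit:
                if b.end - b.start > p.end - p.start:
                    out[-1] = b
                continue
        out.append(b)
    return out


def _segment_periods(period: np.ndarray, max_unit: int,
                     min_run_positions: int = 30) -> list[tuple[int, int, int]]:
    """Runs of positions whose dominant period is consistent."""
    valid = np.flatnonzero(period > 0)
    if valid.size == 0:
        return []
    segments = []
    cur: list[int] = []
    vals: list[int] = []

    def close():
        if len(cur) >= min_run_positions:
            u = int(np.median(vals))
            segments.append((cur[0], cur[-1] + u, u))

    for i in valid:
        p = int(period[i])
        if not cur:
            cur, vals = [i], [p]
            continue
        u = int(np.median(vals[-200:]))
        gap_limit = max(2 * u, 200)
        tol = max(4, int(0.08 * u))
        harmonic = any(abs(p - m * u) <= tol for m in (1, 2, 3))
        if i - cur[-1] > gap_limit or not harmonic:
            close()
            cur, vals = [i], [p]
        else:
            cur.append(i)
            if abs(p - u) <= tol:
                vals.append(p)
    close()
    return segments


def _refine_boundaries(enc: np.ndarray, s: int, e: int, u: int,
                       min_match: float) -> tuple[int, int]:
    """Walk outward while the lag-u self-match stays high."""
    n = enc.size
    w = max(15, u // 4)

    def frac(i: int) -> float:
        j = min(i + w, n - u)
        if j <= i:
            return 0.0
        return float(np.mean(enc[i:j] == enc[i + u:j + u]))

    while s > 0 and frac(max(0, s - w)) >= min_match:
        s = max(0, s - w)
    while s < n - u and frac(s) < min_match:
        s += 1
    end_probe = e - u
    while end_probe + w < n - u and frac(end_probe + 1) >= min_match:
        end_probe += w
    while end_probe > s and frac(end_probe - 1) < min_match:
        end_probe -= 1
    return s, min(n, end_probe + u)


def _refine_unit(enc: np.ndarray, u0: int, max_unit: int) -> int | None:
    span = enc.size
    hi = min(max_unit, span // 2, int(2.2 * u0) + 25)
    lags = np.arange(10, hi + 1)
    if lags.size == 0:
        return None
    ac = np.array([_match_track(enc, int(l)) for l in lags])
    if ac.max() <= 0.45:
        return None
    best = ac.max()
    qualifying = lags[ac >= 0.95 * best]
    return int(qualifying[0]) if qualifying.size else None


def _unit_consensus(seq: str, unit: int) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n_full = arr.size // unit
    if n_full == 0:
        return seq[:unit]
    mat = arr[: n_full * unit].reshape(n_full, unit)
    out = []
    for col in mat.T:
        vals, counts = np.unique(col, return_counts=True)
        out.append(chr(vals[np.argmax(counts)]))
    return "".join(out)


# --------------------------------------------------------------------------
# homoplasmy / variant sites
# --------------------------------------------------------------------------

def pileup(alignments: list[AlignmentRecord], ref: SequenceRecord) -> np.ndarray:
    """Per-base A/C/G/T counts from base-level re-alignment of each record."""
    counts = np.zeros((4, len(ref)), dtype=np.int64)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for a in alignments:
        if a.query_seq is None:
            continue
        if a.strand == "+":
            q = a.query_seq[a.query_start:a.query_end]
        else:
            rc = revcomp(a.query_seq)
            q = rc[a.query_length - a.query_end: a.query_length - a.query_start]
        t = ref.seq[a.target_start:a.target_end]
        res = edlib.align(q, t, mode="NW", task="path")
        qi, ti = 0, a.target_start
        num = ""
        for ch in res["cigar"]:
            if ch.isdigit():
                num += ch
                continue
            length = int(num)
            num = ""
            if ch in "=X":
                for _ in range(length):
                    b = base_idx.get(q[qi])
                    if b is not None:
                        counts[b, ti] += 1
                    qi += 1
                    ti += 1
            elif ch == "I":
                qi += length
            elif ch == "D":
                ti += length
    return counts


def homoplasmy_check(alignments: list[AlignmentRecord], ref: SequenceRecord,
                     coding_region: tuple[int, int], min_depth: int = 10,
                     min_af: float = 0.2) -> list[VariantSite]:
    """Variant sites within the coding region from a short-read pileup.

    A site is a variant if depth >= min_depth and the top non-reference
    allele fraction >= min_af. A coding region with zero depth everywhere
    raises InsufficientDataError - "no data" is not "no variants".
    """
    counts = pileup(alignments, ref)
    s, e = coding_region
    depth = counts[:, s:e].sum(axis=0)
    if depth.max(initial=0) == 0:
        raise InsufficientDataError("no coverage in the coding region")
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    sites: list[VariantSite] = []
    for pos in range(s, e):
        dp = int(counts[:, pos].sum())
        if dp < min_depth:
            continue
        ref_b = ref.seq[pos]
        ri = base_idx.get(ref_b)
        alt_counts = [(int(c), i) for i, c in enumerate(counts[:, pos]) if i != ri]
        alt_n, alt_i = max(alt_counts)
        af = alt_n / dp
        if af >= min_af:
            sites.append(VariantSite(pos=pos, ref_base=ref_b,
                                     alt_base="ACGT"[alt_i], depth=dp,
                                     alt_fraction=round(af, 4)))
    return sites


def gc_track(seq: str, window: int = 40) -> np.ndarray:
    """Windowed GC fraction with step = window (40 bp by convention)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    gc = (arr == ord("G")) | (arr == ord("C"))
    nwin = arr.size // window
    return gc[: nwin * window].reshape(nwin, window).mean(axis=1)
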