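"""Exact k-mer seeding with edlib-based extension.

This is the package's internal stand-in for an external local aligner:
2-bit k-mer hashing over numpy arrays, diagonal-band seed clustering, and
banded edit-distance extension via edlib. Adequate in the >=85% identity
regime the workbench targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def encode(seq: str) -> np.ndarray:
    """Map a sequence to 2-bit codes; ambiguous bases become 255."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling 2-bit k-mer hashes; -1 where the window contains an ambiguous base."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        window = codes[i: i + n]
        out = (out << 2) | np.where(window == 255, 0, window).astype(np.int64)
        bad |= window == 255
    out[bad] = -1
    return out


class KmerIndex:
    """Sorted k-mer index over one target sequence."""

    def __init__(self, seq: str, k: int = 13, max_hits_per_kmer: int = 64):
        self.k = k
        self.seq = seq
        self.max_hits = max_hits_per_kmer
        codes = kmer_codes(encode(seq), k)
        self._order = np.argsort(codes, kind="stable")
        self._sorted = codes[self._order]

    def lookup(self, query: str, step: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """All (query_pos, target_pos) exact k-mer matches, every ``step`` k-mers."""
        qcodes = kmer_codes(encode(query), self.k)
        if qcodes.size == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        qpos_all = np.arange(0, qcodes.size, step)
        qc = qcodes[qpos_all]
        valid = qc >= 0
        qpos_all, qc = qpos_all[valid], qc[valid]
        left = np.searchsorted(self._sorted, qc, side="left")
        right = np.searchsorted(self._sorted, qc, side="right")
        counts = np.minimum(right - left, self.max_hits)
        qpos = np.repeat(qpos_all, counts)
        if qpos.size == 0:
            return qpos, qpos
        tidx = np.concatenate([
            self._order[l: l + c] for l, c in zip(left, counts) if c > 0
        ])
        return qpos, tidx


@dataclass
class SeedCluster:
    qstart: int
    qend: int
    tstart: int
    tend: int
    n_seeds: int

    @property
    def qspan(self) -> int:
        return self.qend - self.qstart


def cluster_seeds(qpos: np.ndarray, tpos: np.ndarray, k: int,
                  band: int = 150, max_gap: int = 2000,
                  min_seeds: int = 3) -> list[SeedCluster]:
    """Group seed matches into colinear clusters.

    Seeds are split on diagonal jumps larger than ``band`` and then on target
    gaps larger than ``max_gap``; each surviving group becomes one cluster.
    """
    if qpos.size == 0:
        return []
    diag = tpos - qpos
    order = np.lexsort((tpos, diag))
    diag, q, t = diag[order], qpos[order], tpos[order]
    breaks = np.flatnonzero(np.diff(diag) > band) + 1
    clusters: list[SeedCluster] = []
    for grp in np.split(np.arange(diag.size), breaks):
        if grp.size == 0:
            continue
        tg, qg = t[grp], q[grp]
        sub = np.argsort(tg, kind="stable")
        tg, qg = tg[sub], qg[sub]
        gaps = np.flatnonzero(np.diff(tg) > max_gap) + 1
        for piece in np.split(np.arange(tg.size), gaps):
            if piece.size < min_seeds:
                continue
            clusters.append(SeedCluster(
                qstart=int(qg[piece].min()), qend=int(qg[piece].max()) + k,
                tstart=int(tg[piece].min()), tend=int(tg[piece].max()) + k,
                n_seeds=int(piece.size),
            ))
    return clusters


def merge_colinear(clusters: list[SeedCluster], max_gap: int = 2000,
                   band: int = 300) -> list[SeedCluster]:
    """Merge clusters that continue each other on a nearby diagonal."""
    if not clusters:
        return []
    clusters = sorted(clusters, key=lambda c: c.tstart)
    merged = [clusters[0]]
    for c in clusters[1:]:
        p = merged[-1]
        dp = p.tstart - p.qstart
        dc = c.tstart - c.qstart
        if (abs(dc - dp) <= band and c.tstart - p.tend <= max_gap
                and c.qstart >= p.qstart):
            merged[-1] = SeedCluster(
                qstart=min(p.qstart, c.qstart), qend=max(p.qend, c.qend),
                tstart=min(p.tstart, c.tstart), tend=max(p.tend, c.tend),
                n_seeds=p.n_seeds + c.n_seeds,
            )
        else:
            merged.append(c)
    return merged


@dataclass
class Extension:
    """Result of extending one seed cluster with edlib."""

    qstart: int
    qend: int
    tstart: int
    tend: int
    distance: int
    identity: float  # percent
    cigar: str | None = None


def extend_cluster(query: str, target: str, cl: SeedCluster, pad: int = 200,
                   full_query: bool = True, task: str = "locations") -> Extension | None:
    """Align the cluster-supported query extent into a padded target window.

    With ``full_query`` the whole query is aligned (infix mode into the
    window); otherwise only the seed-supported query slice, which
    approximates a local alignment for truncated copies.
    """
    if full_query:
        qs, qe = 0, len(query)
        wpad = pad + cl.qstart + (len(query) - cl.qend)
    else:
        qs, qe = max(0, cl.qstart - pad), min(len(query), cl.qend + pad)
        wpad = 2 * pad
    ws = max(0, cl.tstart - (cl.qstart - qs) - wpad)
    we = min(len(target), cl.tend + (qe - cl.qend) + wpad)
    qseq = query[qs:qe]
    if not qseq or we <= ws:
        return None
    res = edlib.align(qseq, target[ws:we], mode="HW", task=task)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc = res["locations"][0]
    tstart, tend = ws + loc[0], ws + loc[1] + 1
    span = max(len(qseq), tend - tstart)
    identity = 100.0 * (1.0 - res["editDistance"] / span)
    return Extension(qstart=qs, qend=qe, tstart=tstart, tend=tend,
                     distance=res["editDistance"], identity=identity,
                     cigar=res.get("cigar"))


def cigar_to_ops(cigar: str) -> list[tuple[int, str]]:
    """Parse an edlib extended cigar string into (length, op) tuples."""
    ops: list[tuple[int, str]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops
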