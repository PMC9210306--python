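"""Hi-C-based organelle-contig validation.

Chromatin contact data distinguish contigs that are physically part of a
chromosome (strong cis contact enrichment with their home pseudo-chromosome)
from free-floating organelle DNA, whose crosslinking to every chromosome sits
at background levels. For a query contig the per-pseudo-chromosome contact
fractions (contacts with chromosome c divided by the contig's total
contacts, self-contacts excluded) are compared against the same profiles for
a panel of background nuclear contigs or windows.

A query is called nuclear-linked to chromosome c when its fraction at c is
both above the robust upper fence of the background trans-fraction
distribution and within the background cis (home-chromosome) distribution's
lower fence; a contig clearing the trans background but far below every
background contig's own-chromosome association - the organelle signature -
is called unlinked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import SequenceRecord
from .synthetic import rng_for


@dataclass
class ContigStats:
    contig: str
    length: int
    gatc_sites: int
    total_contacts: int = 0


@dataclass
class HiCAssociationProfile:
    """Per-pseudo-chromosome normalized contact fractions for one query."""

    query: str
    home_chrom: str | None
    fractions: dict[str, float]
    total_contacts: int
    no_data: bool = False
    gatc_normalized: dict[str, float] = field(default_factory=dict)

    @property
    def max_chrom(self) -> str | None:
        if self.no_data:
            return None
        return max(self.fractions, key=self.fractions.get)


def count_restriction_sites(seq: str | SequenceRecord, motif: str = "GATC") -> int:
    """Occurrences of the motif on the forward strand, counting overlaps.

    GATC (the Sau3AI site) is palindromic, so each physical site is counted
    exactly once.
    """
    if isinstance(seq, SequenceRecord):
        seq = seq.seq
    if not motif:
        raise ValueError("motif must be non-empty")
    count = start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def select_background_contigs(assembly: list[SequenceRecord],
                              size_range: tuple[int, int] = (50_000, 100_000),
                              n_per_chrom: int = 10, seed: int = 0,
                              exclude: tuple[str, ...] = ()) -> list[dict]:
    """Seeded sample of background contigs/windows per pseudo-chromosome.

    When the assembly has no sub-contigs (synthetic case), non-overlapping
    windows with in-range sizes substitute, flagged ``window=True``.
    """
    rng = rng_for(seed, "background-contigs")
    out: list[dict] = []
    deficient: list[str] = []
    for rec in assembly:
        if rec.id in exclude or rec.circular:
            continue
        lo, hi = size_range
        if len(rec) < n_per_chrom * lo:
            deficient.append(rec.id)
            continue
        hi = min(hi, len(rec) // n_per_chrom)
        if hi < lo:
            deficient.append(rec.id)
            continue
        sizes = rng.integers(lo, hi + 1, size=n_per_chrom)
        # lay windows left-to-right with seeded jitter in the leftover slack
        slack = len(rec) - int(sizes.sum())
        gaps = rng.multinomial(slack, np.ones(n_per_chrom + 1) / (n_per_chrom + 1))
        pos = 0
        for w, g in zip(sizes, gaps[:-1]):
            pos += int(g)
            out.append(dict(contig=rec.id, start=pos, end=pos + int(w),
                            chrom=rec.id, window=True))
            pos += int(w)
    if deficient:
        raise ValueError(
            "chromosomes too short for the requested background sample: "
            + ", ".join(deficient)
        )
    return out


def _end_in_query(chrom: pd.Series, pos: pd.Series, query: dict) -> pd.Series:
    m = chrom == query["contig"]
    if query.get("start") is not None:
        m &= (pos >= query["start"]) & (pos < query["end"])
    return m


def contact_profile(pairs: pd.DataFrame, query: dict | str,
                    chrom_assignment: dict[str, str] | None = None,
                    gatc_counts: dict[str, int] | None = None
                    ) -> HiCAssociationProfile:
    """Normalized per-chromosome contact fractions for one query contig/window.

    ``query`` is a contig id, or a dict with contig/start/end (and optionally
    its ``chrom`` home assignment). Self-contacts (both ends in the query)
    are excluded from numerator and denominator. Zero total contacts flags
    the profile ``no_data`` rather than returning silent zeros.
    """
    if isinstance(query, str):
        query = dict(contig=query, start=None, end=None, chrom=None)
    assign = chrom_assignment or {}

    in1 = _end_in_query(pairs["chrom1"], pairs["pos1"], query)
    in2 = _end_in_query(pairs["chrom2"], pairs["pos2"], query)
    partner = pd.concat([
        pairs.loc[in1 & ~in2, "chrom2"],
        pairs.loc[in2 & ~in1, "chrom1"],
    ])
    partner = partner.map(lambda c: assign.get(c, c))
    total = len(partner)
    counts = partner.value_counts()
    chroms = sorted(set(assign.values()) if assign else
                    set(pairs["chrom1"]).union(pairs["chrom2"]))
    fractions = {c: (float(counts.get(c, 0)) / total if total else 0.0)
                 for c in chroms}
    gatc_norm = {}
    if gatc_counts:
        gatc_norm = {c: counts.get(c, 0) / max(gatc_counts.get(c, 1), 1)
                     for c in chroms}
    home = query.get("chrom")
    return HiCAssociationProfile(
        query=str(query["contig"]) + (f":{query['start']}-{query['end']}"
                                      if query.get("start") is not None else ""),
        home_chrom=home, fractions=fractions, total_contacts=total,
        no_data=total == 0, gatc_normalized=gatc_norm,
    )


def contact_profiles(pairs: pd.DataFrame, windows: list[dict],
                     chroms: list[str] | None = None
                     ) -> list[HiCAssociationProfile]:
    """Vectorized contact_profile over a panel of non-overlapping windows.

    Equivalent to calling contact_profile per window, but assigns every pair
    end to its window with searchsorted and accumulates counts in one pass.
    """
    if chroms is None:
        chroms = sorted(set(pairs["chrom1"]).union(pairs["chrom2"]))
    chrom_idx = {c: i for i, c in enumerate(chroms)}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for w_id, w in enumerate(windows):
        by_chrom.setdefault(w["contig"], ([], [], []))
        s, e, i = by_chrom[w["contig"]]
        s.append(w["start"])
        e.append(w["end"])
        i.append(w_id)
    by_chrom = {c: (np.array(s), np.array(e), np.array(i))
                for c, (s, e, i) in by_chrom.items()}

    def window_of(chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        out = np.full(pos.size, -1, dtype=np.int64)
        for c, (starts, ends, wids) in by_chrom.items():
            m = chrom == c
            if not m.any():
                continue
            order = np.argsort(starts)
            st, en, wi = starts[order], ends[order], wids[order]
            j = np.searchsorted(st, pos[m], side="right") - 1
            ok = (j >= 0) & (pos[m] < en[np.clip(j, 0, None)])
            tmp = np.full(int(m.sum()), -1, dtype=np.int64)
            tmp[ok] = wi[j[ok]]
            out[m] = tmp
        return out

    c1 = pairs["chrom1"].to_numpy()
    c2 = pairs["chrom2"].to_numpy()
    w1 = window_of(c1, pairs["pos1"].to_numpy())
    w2 = window_of(c2, pairs["pos2"].to_numpy())
    counts = np.zeros((len(windows), len(chroms)), dtype=np.int64)
    p1 = (w1 >= 0) & (w1 != w2)  # self-contacts (same window both ends) excluded
    p2 = (w2 >= 0) & (w1 != w2)
    ci2 = np.array([chrom_idx[c] for c in c2[p1]])
    ci1 = np.array([chrom_idx[c] for c in c1[p2]])
    if ci2.size:
        np.add.at(counts, (w1[p1], ci2), 1)
    if ci1.size:
        np.add.at(counts, (w2[p2], ci1), 1)
    profiles = []
    for w_id, w in enumerate(windows):
        total = int(counts[w_id].sum())
        fr = {c: (counts[w_id, i] / total if total else 0.0)
              for c, i in chrom_idx.items()}
        profiles.append(HiCAssociationProfile(
            query=f"{w['contig']}:{w['start']}-{w['end']}",
            home_chrom=w.get("chrom"), fractions=fr, total_contacts=total,
            no_data=total == 0,
        ))
    return profiles


@dataclass
class ContigClassification:
    query: str
    classification: str          # "nuclear-linked" | "unlinked"
    chromosome: str | None
    max_fraction: float
    effect_size: float
    trans_fence: float
    cis_floor: float


def classify_contig(query_profile: HiCAssociationProfile,
                    background_profiles: list[HiCAssociationProfile],
                    k: float = 1.5) -> ContigClassification:
    """Classify a query contig as nuclear-linked or unlinked.

    The query's maximal per-chromosome fraction must clear two robust fences
    derived from the background panel: above median + k*IQR of the background
    trans fractions (it is not mere background crosslinking) and at least
    median - k*IQR of the background cis (home-chromosome) fractions (it is
    comparable to a genuinely linked contig). Effect size is
    (max query fraction - trans median) / trans IQR.
    """
    if query_profile.no_data:
        raise InsufficientHiCData(f"query {query_profile.query} has no contacts")
    if len(background_profiles) < 30:
        raise ValueError("need at least 30 background profiles")

    trans, trans_max, cis = [], [], []
    for p in background_profiles:
        if p.no_data or p.home_chrom is None:
            continue
        tf = [f for c, f in p.fractions.items() if c != p.home_chrom]
        trans.extend(tf)
        trans_max.append(max(tf))
        cis.append(p.fractions.get(p.home_chrom, 0.0))
    trans = np.asarray(trans)
    trans_max = np.asarray(trans_max)
    cis = np.asarray(cis)
    t_med, t_iqr = float(np.median(trans)), float(np.subtract(*np.percentile(trans, [75, 25])))
    tm_med, tm_iqr = float(np.median(trans_max)), float(np.subtract(*np.percentile(trans_max, [75, 25])))
    c_med, c_iqr = float(np.median(cis)), float(np.subtract(*np.percentile(cis, [75, 25])))
    # fence on the comparable statistic: a window's LARGEST trans fraction
    trans_fence = tm_med + k * tm_iqr
    cis_floor = c_med - k * c_iqr

    best_c = query_profile.max_chrom
    best_f = query_profile.fractions[best_c]
    others = [f for c, f in query_profile.fractions.items() if c != best_c]
    runner_up = max(others) if others else 0.0
    # linkage shows one dominant chromosome: the top fraction must clear the
    # background fences AND stand out from the query's own runner-up
    linked = (best_f > trans_fence and best_f >= cis_floor
              and best_f - runner_up > k * t_iqr)
    effect = (best_f - t_med) / t_iqr if t_iqr > 0 else float("inf")
    return ContigClassification(
        query=query_profile.query,
        classification="nuclear-linked" if linked else "unlinked",
        chromosome=best_c if linked else None,
        max_fraction=round(best_f, 6), effect_size=round(effect, 3),
        trans_fence=round(trans_fence, 6), cis_floor=round(cis_floor, 6),
    )


class InsufficientHiCData(ValueError):
    """Query profile has no contacts; classification refused."""


def profiles_to_long(profiles: list[HiCAssociationProfile]) -> pd.DataFrame:
    """Boxplot-ready long format: one row per (contig, chromosome, fraction)."""
    rows = []
    for p in profiles:
        for c, f in p.fractions.items():
            rows.append(dict(contig=p.query, chromosome=c, fraction=f,
                             is_home=c == p.home_chrom))
    return pd.DataFrame(rows)


def shuffle_pairs(pairs: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Permutation null: re-pair contact partners at random."""
    rng = rng_for(seed, "pair-shuffle")
    out = pairs.copy()
    perm = rng.permutation(len(out))
    out[["chrom2", "pos2"]] = out[["chrom2", "pos2"]].to_numpy()[perm]
    return out
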