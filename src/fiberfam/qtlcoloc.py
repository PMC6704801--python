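"""QTL anchoring, same-trait hotspot detection, and gene co-localization.

A QTL hotspot is a genomic region where at least ``min_count`` QTL for the
same trait from independent studies cluster within a ``window``-cM interval
of the genetic map (defaults 4 and 20 cM).  Hotspot intervals are anchored
to physical coordinates by piecewise-linear interpolation between markers
carrying both a cM and a bp position, and genes are assigned to hotspots by
half-open interval overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GeneModel

__all__ = [
    "MarkerAnchor",
    "QtlRecord",
    "Hotspot",
    "Colocalization",
    "filter_anchors",
    "anchor_to_bp",
    "detect_hotspots",
    "colocalize",
]


@dataclass(frozen=True)
class MarkerAnchor:
    """A marker with both a genetic (cM) and a physical (bp) position."""

    marker_id: str
    chrom: str
    cM: float
    bp: int


@dataclass(frozen=True)
class QtlRecord:
    """A mapped QTL with a cM peak (midpoint of its support interval when
    only an interval is reported)."""

    qtl_id: str
    trait: str
    chrom: str
    cM: float
    cM_start: float | None = None
    cM_end: float | None = None
    source: str = ""

    @classmethod
    def from_interval(
        cls, qtl_id: str, trait: str, chrom: str, cM_start: float, cM_end: float, source: str = ""
    ) -> "QtlRecord":
        return cls(qtl_id, trait, chrom, (cM_start + cM_end) / 2.0, cM_start, cM_end, source)


@dataclass
class Hotspot:
    hotspot_id: str
    trait: str
    chrom: str
    cM_lo: float
    cM_hi: float
    member_qtl_ids: list[str]
    bp_lo: int | None = None
    bp_hi: int | None = None

    @property
    def qtl_count(self) -> int:
        return len(self.member_qtl_ids)


@dataclass
class Colocalization:
    gene_id: str
    hotspot_ids: list[str] = field(default_factory=list)
    traits: list[str] = field(default_factory=list)


def filter_anchors(anchors: list[MarkerAnchor]) -> list[MarkerAnchor]:
    """Greedily drop anchors violating joint cM/bp monotonicity.

    Real genetic maps contain local inversions; the longest strictly
    increasing subsequence in bp (anchors ordered by cM) is kept, which
    leaves a set monotone in both coordinates.
    """
    ordered = sorted(anchors, key=lambda a: (a.cM, a.bp))
    if not ordered:
        return []
    # longest strictly increasing subsequence in bp, O(n^2) — anchor sets are small
    n = len(ordered)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if ordered[j].bp < ordered[i].bp and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    idx = int(np.argmax(best_len))
    keep: list[MarkerAnchor] = []
    while idx >= 0:
        keep.append(ordered[idx])
        idx = prev[idx]
    return keep[::-1]


def anchor_to_bp(cM: float, anchors: list[MarkerAnchor]) -> int:
    """Interpolate a genetic position to bp between its bracketing anchors.

    Outside the anchored range the position is clamped to the nearest
    anchor's bp.  Requires >= 2 (monotone, same-chromosome) anchors.
    """
    usable = filter_anchors(anchors)
    if len(usable) < 2:
        dropped = sorted({a.marker_id for a in anchors} - {a.marker_id for a in usable})
        detail = f" (dropped non-monotone markers {dropped})" if dropped else ""
        raise ValueError(f"need at least 2 monotone anchors for interpolation{detail}")
    if len({a.chrom for a in usable}) > 1:
        raise ValueError("anchors span multiple chromosomes")
    cms = np.array([a.cM for a in usable])
    bps = np.array([a.bp for a in usable], dtype=float)
    return int(round(float(np.interp(cM, cms, bps))))


def detect_hotspots(
    qtls: list[QtlRecord],
    window: float = 20.0,
    min_count: int = 4,
    anchors: dict[str, list[MarkerAnchor]] | None = None,
) -> list[Hotspot]:
    """Detect same-trait QTL clusters on the genetic map.

    Per (trait, chromosome): peaks are sorted; a candidate window
    ``[peak, peak + window]`` is anchored at every peak; windows holding at
    least *min_count* peaks are kept; overlapping kept windows are merged
    (so a merged hotspot may span more than one window); the reported
    interval is the [min, max] of member peaks.  Hotspots of different
    traits are never merged.  Ids follow ``{trait}_Hotspot_{chrom}`` with an
    ``_k`` ordinal suffix when a trait has several hotspots on one
    chromosome.  When *anchors* (chrom -> anchor list) is given, bp
    intervals are interpolated.
    """
    groups: dict[tuple[str, str], list[QtlRecord]] = {}
    for q in qtls:
        groups.setdefault((q.trait, q.chrom), []).append(q)

    hotspots: list[Hotspot] = []
    for (trait, chrom) in sorted(groups):
        members = sorted(groups[(trait, chrom)], key=lambda q: (q.cM, q.qtl_id))
        peaks = np.array([q.cM for q in members])
        kept: list[tuple[float, float]] = []
        for peak in peaks:
            inside = (peaks >= peak) & (peaks <= peak + window)
            if int(inside.sum()) >= min_count:
                kept.append((peak, peak + window))
        if not kept:
            continue
        # merge overlapping kept windows
        merged: list[list[float]] = []
        for lo, hi in kept:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        per_chrom: list[Hotspot] = []
        for lo, hi in merged:
            member_ids = [q.qtl_id for q in members if lo <= q.cM <= hi]
            member_cms = [q.cM for q in members if lo <= q.cM <= hi]
            per_chrom.append(
                Hotspot(
                    hotspot_id="",  # assigned below once ordinals are known
                    trait=trait,
                    chrom=chrom,
                    cM_lo=min(member_cms),
                    cM_hi=max(member_cms),
                    member_qtl_ids=member_ids,
                )
            )
        for k, hs in enumerate(per_chrom, start=1):
            suffix = f"_{k}" if len(per_chrom) > 1 else ""
            hs.hotspot_id = f"{trait}_Hotspot_{chrom}{suffix}"
            if anchors and chrom in anchors:
                hs.bp_lo = anchor_to_bp(hs.cM_lo, anchors[chrom])
                hs.bp_hi = anchor_to_bp(hs.cM_hi, anchors[chrom])
        hotspots.extend(per_chrom)

    for hs in hotspots:  # output sanity contract
        assert hs.qtl_count >= min_count
    return hotspots


def colocalize(
    genes: list[GeneModel], hotspots: list[Hotspot]
) -> tuple[list[Colocalization], list[str]]:
    """Assign genes to hotspots by half-open bp interval overlap.

    A gene overlaps a hotspot iff ``gene.start < bp_hi and bp_lo <
    gene.end`` on the same chromosome (abutting intervals do not overlap).
    Genes on chromosomes carrying no anchored hotspot are returned in the
    second element as unplaced.  Output is sorted by (chrom, start).
    """
    anchored = [h for h in hotspots if h.bp_lo is not None and h.bp_hi is not None]
    chroms_with_hotspots = {h.chrom for h in anchored}
    out: list[Colocalization] = []
    unplaced: list[str] = []
    for gene in sorted(genes, key=lambda g: (g.chrom, g.start)):
        if gene.chrom not in chroms_with_hotspots:
            unplaced.append(gene.gene_id)
            continue
        hits = [
            h
            for h in anchored
            if h.chrom == gene.chrom and gene.start < h.bp_hi and h.bp_lo < gene.end
        ]
        if hits:
            out.append(
                Colocalization(
                    gene.gene_id,
                    [h.hotspot_id for h in hits],
                    sorted({h.trait for h in hits}),
                )
            )
    return out, unplaced
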