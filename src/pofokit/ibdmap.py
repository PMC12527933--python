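"""Identity-by-descent segment detection against surrogate-parent groups.

Segments are found by scanning for long identity runs between a target
haplotype and either haplotype of a group member, with a bounded mismatch
tolerance standing in for the error absorption of an HMM-based IBD mapper:
runs are split wherever two consecutive sites mismatch, and any candidate
whose internal mismatch fraction exceeds the tolerance is split further.
Segments shorter than 3 cM (sex-averaged) are discarded; overlapping
segments from members of the same group are merged.

Coordinates are 0-based half-open bp throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .maps import GeneticMap

__all__ = ["IbdSegment", "interpolate_cm", "detect_ibd", "longest_x_share"]

MIN_CM_DEFAULT = 3.0


@dataclass(frozen=True)
class IbdSegment:
    chrom: str
    start: int          # bp, inclusive
    end: int            # bp, exclusive
    length_cm: float    # sex-averaged
    hap: int            # target haplotype index, 0 or 1
    group: str          # G1 / G2 (or a member id when no grouping applies)
    member: object      # id of the relative whose haplotype matched

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


def interpolate_cm(gmap: GeneticMap, chrom: str, bp) -> tuple:
    """Female and male cM at ``bp`` (clamped to the map range)."""
    return gmap.interpolate(chrom, bp, sex=None)


# --------------------------------------------------------------------------- #
def _match_runs(
    a: np.ndarray, b: np.ndarray, max_mismatch_rate: float,
    min_merge_run: int = 8,
) -> list[tuple[int, int]]:
    """Maximal identity runs of ``a`` vs ``b`` in site-index space.

    Returns half-open (i, j) site intervals.  Exact matching runs are
    merged greedily across isolated single-site mismatches as long as the
    merged span's mismatch density stays within ``max_mismatch_rate`` and
    the runs on both sides of the mismatch span at least ``min_merge_run``
    sites — the latter stops long segments from eroding outwards through
    short chance runs beyond their true boundary.  With
    ``max_mismatch_rate=0`` this reduces to exact maximal runs.
    """
    n = len(a)
    mism = np.flatnonzero(a != b)
    if len(mism) == 0:
        return [(0, n)] if n else []
    bounds = np.concatenate([[-1], mism, [n]])
    starts = bounds[:-1] + 1
    ends = bounds[1:]
    keep = ends > starts
    runs = list(zip(starts[keep].tolist(), ends[keep].tolist()))
    if max_mismatch_rate <= 0 or len(runs) < 2:
        return runs
    # greedy left-to-right merge across isolated mismatches, keeping the
    # merged mismatch density within tolerance
    merged: list[tuple[int, int]] = []
    cs, ce = runs[0]
    cm = 0
    tail = ce - cs
    for s, e in runs[1:]:
        if (s - ce == 1 and tail >= min_merge_run
                and e - s >= min_merge_run
                and (cm + 1) / (e - cs) <= max_mismatch_rate):
            cm += 1
            ce = e
            tail = e - s
        else:
            merged.append((cs, ce))
            cs, ce, cm = s, e, 0
            tail = e - s
    merged.append((cs, ce))
    return merged


def _merge_intervals(iv: list[tuple[int, int, object]]) -> list[tuple[int, int, object]]:
    """Union of bp intervals; keeps the member contributing the longest piece."""
    if not iv:
        return []
    iv = sorted(iv)
    merged = [list(iv[0]) + [iv[0][1] - iv[0][0]]]
    for s, e, m in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            if e - s > merged[-1][3]:
                merged[-1][2], merged[-1][3] = m, e - s
        else:
            merged.append([s, e, m, e - s])
    return [(s, e, m) for s, e, m, _ in merged]


def detect_ibd(
    target_haps: np.ndarray,
    group_haps: Mapping[object, np.ndarray],
    positions: np.ndarray,
    gmap: GeneticMap,
    chrom: str,
    group: str = "G1",
    min_cm: float = MIN_CM_DEFAULT,
    max_mismatch_rate: float = 0.01,
    min_sites: int = 32,
) -> list[IbdSegment]:
    """IBD segments between a target's haplotypes and a surrogate-parent group.

    ``target_haps`` is (n_haps, n_sites); ``group_haps`` maps member id to a
    (n_haps, n_sites) array on the same variant grid.  For each target
    haplotype, identity runs against every member haplotype are located,
    converted to bp/cM, filtered at ``min_cm``, and merged across members of
    the group.

    ``min_sites`` additionally requires each identity run to span that many
    genotyped sites, so that chance identity between unrelated haplotypes
    cannot masquerade as a segment where markers are sparse.
    """
    if target_haps.shape[-1] != len(positions):
        raise ValueError("haplotypes and positions disagree")
    if len(positions) == 0:
        return []
    segments: list[IbdSegment] = []
    for hap_idx in range(target_haps.shape[0]):
        t = target_haps[hap_idx]
        raw: list[tuple[int, int, object]] = []
        for member, haps in group_haps.items():
            for mh in np.atleast_2d(haps):
                for i, j in _match_runs(t, mh, max_mismatch_rate):
                    if j - i >= min_sites:
                        raw.append((int(positions[i]),
                                    int(positions[j - 1]) + 1, member))
        for s, e, member in _merge_intervals(raw):
            cm_s = gmap.interpolate(chrom, s, "avg")
            cm_e = gmap.interpolate(chrom, e, "avg")
            length = float(cm_e - cm_s)
            if length >= min_cm:
                segments.append(
                    IbdSegment(chrom, s, e, length, hap_idx, group, member)
                )
    return sorted(segments, key=lambda s: (s.hap, s.start))


def longest_x_share(
    target_x: np.ndarray,
    group_x: Mapping[object, np.ndarray],
    positions: np.ndarray,
    gmap: GeneticMap,
    min_cm: float = MIN_CM_DEFAULT,
    chrom: str = "X",
) -> float:
    """Length (cM) of the largest X-chromosome IBD segment with a group.

    ``target_x`` is (1, nx) for males (the single maternal X) or (2, nx) for
    females; both female haplotypes are scanned and the maximum returned.
    Returns 0.0 when no segment reaches the detection floor.
    """
    if target_x.size == 0:
        raise ValueError("no X data for target")
    segs = detect_ibd(
        np.atleast_2d(target_x), group_x, positions, gmap, chrom,
        min_cm=min_cm,
    )
    return max((s.length_cm for s in segs), default=0.0)
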