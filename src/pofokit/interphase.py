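"""Interchromosomal phasing.

Haplotype segments shared IBD with the same surrogate-parent side must all
descend from the same parent, so they must sit on the same haplotype index
on every chromosome.  :func:`scaffold_phase` re-orients observed haplotypes
between consecutive IBD anchors so that every G1 anchor lands on haplotype
index 0 and every G2 anchor on index 1, simultaneously correcting switch
errors between anchors of the same side.  :func:`pedigree_phase` resolves
parent-of-origin directly by transmission logic when parents are genotyped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ibdmap import IbdSegment

__all__ = [
    "pedigree_phase",
    "scaffold_phase",
    "phasing_metrics",
    "ScaffoldResult",
]


def pedigree_phase(
    child: np.ndarray,
    father: np.ndarray | None = None,
    mother: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign child alleles to paternal/maternal haplotypes by transmission.

    Genotypes are 0/1/2 vectors.  Returns ``(hap_pat, hap_mat, mask)``:
    haplotypes carry -1 where unresolvable (e.g. all-heterozygous sites);
    ``mask`` flags Mendel-inconsistent sites, which are left unresolved.
    With one parent, the other side is deduced by exclusion.
    """
    if father is None and mother is None:
        raise ValueError("at least one parent required")
    c = np.asarray(child)
    n = len(c)
    hp = np.full(n, -1, dtype=np.int8)
    hm = np.full(n, -1, dtype=np.int8)
    # homozygous child: both haplotypes known regardless of parents
    hp[c == 0] = 0
    hm[c == 0] = 0
    hp[c == 2] = 1
    hm[c == 2] = 1
    het = c == 1

    def allele_bounds(g):
        if g is None:
            return np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8)
        g = np.asarray(g)
        return (g == 2).astype(np.int8), (g > 0).astype(np.int8)

    f_min, f_max = allele_bounds(father)
    m_min, m_max = allele_bounds(mother)
    mendel_bad = (c < f_min + m_min) | (c > f_max + m_max)
    # het child: resolvable where one parent's transmitted allele is forced
    forced_f = f_min == f_max
    forced_m = m_min == m_max
    res_f = het & forced_f & ~mendel_bad
    hp[res_f] = f_min[res_f]
    hm[res_f] = 1 - f_min[res_f]
    res_m = het & forced_m & ~forced_f & ~mendel_bad
    hm[res_m] = m_min[res_m]
    hp[res_m] = 1 - m_min[res_m]
    hp[mendel_bad] = -1
    hm[mendel_bad] = -1
    return hp, hm, mendel_bad


@dataclass
class ScaffoldResult:
    """Output of :func:`scaffold_phase`."""

    haplotypes: dict                      # chrom -> (2, n_sites)
    anchored: dict                        # chrom -> bool
    flips: dict = field(default_factory=dict)   # chrom -> flip positions (bp)

    def unanchored(self) -> list:
        return [c for c, ok in self.anchored.items() if not ok]


def _anchor_swap(seg: IbdSegment) -> int:
    """1 if the haplotype pair must be swapped to put this anchor's side on
    its canonical index (G1 -> hap0, G2 -> hap1)."""
    want_hap = 0 if seg.group == "G1" else 1
    return int(seg.hap != want_hap)


def scaffold_phase(
    observed: Mapping[str, np.ndarray],
    positions: Mapping[str, np.ndarray],
    segments: Sequence[IbdSegment],
) -> ScaffoldResult:
    """Re-orient observed haplotypes so G1 anchors sit on haplotype 0.

    ``observed`` maps chromosome to a (2, n_sites) haplotype pair;
    ``segments`` are side-labelled IBD anchors (>=3 cM each).  Between two
    anchors demanding different orientations the flip point is placed at
    the bp midpoint of the inter-anchor gap; chromosomes without anchors are
    returned in input orientation and flagged unanchored.  Applying the
    operation twice is idempotent: anchors of an already consistent pair
    demand no flips.
    """
    by_chrom: dict[str, list[IbdSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    out: dict[str, np.ndarray] = {}
    anchored: dict[str, bool] = {}
    flips: dict[str, list[float]] = {}
    for chrom, haps in observed.items():
        pos = np.asarray(positions[chrom])
        segs = sorted(by_chrom.get(chrom, []), key=lambda s: s.start)
        if not segs:
            out[chrom] = haps.copy()
            anchored[chrom] = False
            flips[chrom] = []
            continue
        # one orientation demand per anchor, resolved left to right
        demands = [(s.start, s.end, _anchor_swap(s)) for s in segs]
        flip_at: list[float] = []
        state = demands[0][2]
        states = [state]
        for k in range(1, len(demands)):
            want = demands[k][2]
            if want != states[-1]:
                # midpoint of the inter-anchor gap; for overlapping anchors
                # (e.g. around a switch error) this is the overlap midpoint
                at = 0.5 * (demands[k - 1][1] + demands[k][0])
                if flip_at and at < flip_at[-1]:
                    at = flip_at[-1]
                flip_at.append(at)
            states.append(want)
        swap = (demands[0][2] + np.searchsorted(
            np.asarray(flip_at), pos, side="right")) % 2 == 1
        fixed = haps.copy()
        fixed[:, swap] = fixed[::-1][:, swap]
        out[chrom] = fixed
        anchored[chrom] = True
        flips[chrom] = flip_at
    return ScaffoldResult(haplotypes=out, anchored=anchored, flips=flips)


def phasing_metrics(
    inferred: Mapping[str, np.ndarray],
    truth: Mapping[str, np.ndarray],
) -> dict:
    """Switch-error rate and interchromosomal concordance against truth.

    Truth haplotypes are PofO-ordered (index 0 paternal).  At each truth
    heterozygous site the inferred pair is oriented either parallel (hap0
    carries the paternal allele) or flipped; the switch-error rate is the
    fraction of consecutive het-site pairs whose orientation changes.  Each
    chromosome gets a majority-vote parental label for inferred haplotype 0;
    interchromosomal concordance is the fraction of chromosomes agreeing
    with the genome-wide majority assignment.
    """
    n_flips = 0
    n_pairs = 0
    chrom_votes: dict[str, int] = {}
    for chrom, true_haps in truth.items():
        inf = inferred[chrom]
        het = true_haps[0] != true_haps[1]
        if het.sum() == 0:
            continue
        # orientation 0: inferred hap0 matches truth paternal allele
        ori = (inf[0][het] != true_haps[0][het]).astype(int)
        n_flips += int((np.diff(ori) != 0).sum())
        n_pairs += len(ori) - 1
        chrom_votes[chrom] = int(round(ori.mean()))  # 0 -> hap0 paternal
    if not chrom_votes:
        return {"switch_error_rate": np.nan,
                "interchromosomal_concordance": np.nan}
    votes = np.array(list(chrom_votes.values()))
    majority = int(round(votes.mean()))
    concordance = float((votes == majority).mean())
    ser = n_flips / n_pairs if n_pairs > 0 else 0.0
    return {
        "switch_error_rate": float(ser),
        "interchromosomal_concordance": concordance,
        "chromosome_labels": {
            c: ("P" if v == 0 else "M") for c, v in chrom_votes.items()
        },
    }
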