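"""Parent-of-origin inference from sibling crossovers.

IBD segment breakends between a sibling pair mark crossovers in the parental
meioses.  Sex-specific recombination maps differ strongly at a local scale,
so the genetic length of a small window around a crossover under the female
map versus the male map,

    Delta(p) = log10(D_f(p)) - log10(D_m(p)),

is negative where male recombination dominates and positive where female
recombination dominates.  Crossovers detected on one haplotype of a sibling
all come from the same parent, so per-chromosome scores
``S_c = sum(Delta on hap0) - sum(Delta on hap1)`` and the genome score
``S = sum_c S_c`` separate the two parents: a negative score means
haplotype 0 is paternally inherited.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ibdmap import IbdSegment
from .maps import GeneticMap
from .parentside import ParentSidePrediction, empirical_side_probability

__all__ = [
    "CrossoverCall",
    "infer_crossovers",
    "delta",
    "chrom_score",
    "genome_score",
    "qc_crossovers",
    "prob_pofo_sib",
    "single_chrom_assign",
]

WINDOW_BP = 500            # half-width of the 1,000-bp crossover window
MORGAN_FLOOR = 1e-8        # floor for zero-length windows before log10
SINGLE_CHROM_THRESHOLD = 2.0
LENGTH_WINDOW_MORGANS = 3.0


@dataclass
class CrossoverCall:
    chrom: str
    pos: int               # breakend bp
    hap: int               # target haplotype whose sharing state changed
    d_female: float = np.nan   # window length, Morgans, female map
    d_male: float = np.nan
    delta: float = np.nan


def infer_crossovers(
    segments: Sequence[IbdSegment],
    positions: Mapping[str, np.ndarray],
    min_cm: float = 3.0,
) -> list[CrossoverCall]:
    """Crossover calls from sibling IBD segment breakends.

    ``segments`` are the target's per-haplotype IBD segments against the
    sibling (already length-filtered at ``min_cm``).  Interior boundaries of
    the per-haplotype sharing profile emit calls; boundaries at chromosome
    ends (first/last genotyped site) are not breakends.
    """
    calls: list[CrossoverCall] = []
    by_key: dict[tuple[str, int], list[IbdSegment]] = {}
    for seg in segments:
        if seg.length_cm < min_cm:
            continue
        by_key.setdefault((seg.chrom, seg.hap), []).append(seg)
    for (chrom, hap), segs in sorted(by_key.items()):
        pos = positions[chrom]
        first, last = int(pos[0]), int(pos[-1])
        for seg in segs:
            for bp in (seg.start, seg.end):
                if first < bp < last:
                    calls.append(CrossoverCall(chrom, int(bp), hap))
    return calls


def delta(call: CrossoverCall, gmap: GeneticMap) -> float:
    """Delta(p) for one crossover: the 1,000-bp window around the breakend
    is measured in Morgans on the female and male maps (clamped at map
    ends, floored at 1e-8 Morgan) and compared on the log10 scale.  The
    call is annotated in place and Delta returned."""
    lo, hi = gmap.span_bp(call.chrom)
    a = max(call.pos - WINDOW_BP, lo)
    b = min(call.pos + WINDOW_BP, hi)
    f_a, m_a = gmap.interpolate(call.chrom, a)
    f_b, m_b = gmap.interpolate(call.chrom, b)
    d_f = max((f_b - f_a) / 100.0, MORGAN_FLOOR)
    d_m = max((m_b - m_a) / 100.0, MORGAN_FLOOR)
    call.d_female, call.d_male = d_f, d_m
    call.delta = float(np.log10(d_f) - np.log10(d_m))
    return call.delta


def chrom_score(calls: Sequence[CrossoverCall], gmap: GeneticMap | None = None
                ) -> float:
    """S_c: sum of Delta over haplotype-0 calls minus haplotype-1 calls."""
    s = 0.0
    for call in calls:
        d = call.delta
        if not np.isfinite(d):
            if gmap is None:
                raise ValueError("call lacks Delta and no map was provided")
            d = delta(call, gmap)
        s += d if call.hap == 0 else -d
    return float(s)


def genome_score(chrom_scores: Sequence[float]) -> float:
    """S: the per-chromosome scores added up across chromosomes."""
    return float(np.sum(chrom_scores))


def qc_crossovers(
    counts: pd.DataFrame, l_c: Mapping[str, float] | None = None,
    iqr_factor: float = 10.0, poisson_tail: float = 1e-6,
) -> pd.DataFrame:
    """Flag individuals with aberrant per-chromosome crossover counts.

    ``counts`` has columns ``iid``, ``chrom``, ``n_obs``.  Within each
    chromosome the cohort distribution of counts is summarised by quartiles;
    individuals outside ``[Q1 - 10*IQR, Q3 + 10*IQR]`` are dropped for that
    chromosome.  When the IQR degenerates to zero the fallback is a
    two-sided Poisson tail test at ``poisson_tail`` with mean ``4*l_c``
    (the expected count over the four parental meioses of a sibling pair);
    ``l_c`` maps chromosome to its sex-averaged length in Morgans.
    """
    out = counts.copy()
    keep = np.ones(len(out), dtype=bool)
    for chrom, sub in out.groupby("chrom"):
        if len(sub) < 30:
            continue
        q1, q3 = np.percentile(sub["n_obs"], [25, 75])
        iqr = q3 - q1
        if iqr > 0:
            lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
            bad = (sub["n_obs"] < lo) | (sub["n_obs"] > hi)
        else:
            if l_c is None or chrom not in l_c:
                raise ValueError(
                    f"degenerate IQR on {chrom} and no map length given"
                )
            lam = 4.0 * l_c[chrom]
            cdf = stats.poisson.cdf(sub["n_obs"], lam)
            sf = stats.poisson.sf(sub["n_obs"] - 1, lam)
            bad = np.minimum(cdf, sf) < poisson_tail
        keep[sub.index[np.asarray(bad)]] = False
    out["keep"] = keep
    return out


def prob_pofo_sib(
    s_t: float,
    l_t: float,
    validation: pd.DataFrame,
    length_window: float = LENGTH_WINDOW_MORGANS,
    target=None,
) -> ParentSidePrediction:
    """Pr_pat for a genome score ``S_t`` computed over ``l_t`` Morgans.

    ``validation`` holds reference individuals with known haplotype-0 parent:
    columns ``score``, ``length`` (Morgans) and ``h0_parent`` ('pat'/'mat').
    Only reference scores whose genomic length lies within
    ``(l_t - 3, l_t + 3)`` Morgans are compared; an empty window is widened
    stepwise.  Negative scores are compatible with a paternal haplotype 0,
    so the paternal class is the low-score class of the empirical-ratio
    estimator; Pr_mat = 1 - Pr_pat.
    """
    win = length_window
    while True:
        sub = validation[np.abs(validation["length"] - l_t) < win]
        pat = sub.loc[sub["h0_parent"] == "pat", "score"].to_numpy(dtype=float)
        mat = sub.loc[sub["h0_parent"] == "mat", "score"].to_numpy(dtype=float)
        if min(len(pat), len(mat)) >= min(3, (validation["h0_parent"]
                                               .value_counts().min() or 0)):
            if len(pat) and len(mat):
                break
        if win > 10 * max(length_window, 1.0) + validation["length"].abs().max():
            raise ValueError("validation set cannot support this length")
        win += length_window
    side, prob = empirical_side_probability(s_t, pat, mat,
                                            orientation="pat_low")
    return ParentSidePrediction(target, None, "SIB", float(s_t), side, prob)


def single_chrom_assign(s_c: float, threshold: float = SINGLE_CHROM_THRESHOLD
                        ) -> str:
    """Hard-threshold call from one chromosome's score: below -2 the first
    haplotype is paternal, above +2 maternal, otherwise undetermined."""
    if s_c < -threshold:
        return "pat"
    if s_c > threshold:
        return "mat"
    return "undetermined"
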