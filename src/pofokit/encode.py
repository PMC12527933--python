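"""Final PofO calls and probability-weighted parental encodings.

Per-target predictions from the X chromosome, mtDNA MVS, the sibling
crossover score and (when available) actual parental genomes are combined
into a single call for the parent of haplotype 0, with assignment
probability ``p_t``.  Parental allele dosages are then weighted by ``p_t``:

    DS_mat = AP_mat * p_t + AP_pat * (1 - p_t)       (DS_pat symmetric)

and expanded into haploid genotype-probability triplets GP_mat / GP_pat and
the heterozygote-only differential triplet GP_diff, the regressors of the
maternal, paternal and differential association scans.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .parentside import ParentSidePrediction

__all__ = [
    "PofoCall",
    "PofoEncoding",
    "combine_predictors",
    "encode_pofo",
    "filter_variants",
]

#: tie-break priority when predictors disagree at equal probability
PREDICTOR_PRIORITY = ("PED", "X", "SIB", "MT")
HIGH_CONFIDENCE = 0.99


@dataclass
class PofoCall:
    target: object
    h0_parent: str          # 'P' or 'M' (haplotype 1 gets the other parent
    p_t: float              #  by exclusion, assuming no uniparental disomy)
    predictor: str
    high_confidence: bool
    undetermined: bool = False
    reason: str | None = None


def _h0_parent(pred: ParentSidePrediction) -> tuple[str, float]:
    """Convert a side prediction into (hap0 parent, probability).

    X/MT predictions refer to the G1 surrogate side, which scaffold phasing
    pinned to haplotype 0; SIB predictions refer to haplotype 0 directly.
    """
    if pred.side == "pat":
        return "P", pred.probability
    return "M", pred.probability


def combine_predictors(
    predictions: Sequence[ParentSidePrediction], target=None
) -> PofoCall:
    """One PofO call per target from its available predictors.

    The predictor with the highest estimated probability wins; exact ties
    fall back to the priority order parental genomes > X > sib-score > MVS.
    Conflicting mtDNA calls from different 3rd/4th-degree relatives leave
    the target undetermined when MVS would otherwise decide.
    """
    preds = [p for p in predictions if p is not None]
    if not preds:
        raise ValueError("no predictions supplied")
    if target is None:
        target = preds[0].target
    ped = [p for p in preds if p.predictor == "PED"]
    if ped:
        parent, prob = _h0_parent(ped[0])
        return PofoCall(target, parent, prob, "PED", prob >= HIGH_CONFIDENCE)
    order = {name: k for k, name in enumerate(PREDICTOR_PRIORITY)}
    best = sorted(preds, key=lambda p: (-p.probability, order[p.predictor]))[0]
    if best.predictor == "MT":
        distant = [p for p in preds
                   if p.predictor == "MT" and (p.degree or 0) >= 3]
        sides = {p.side for p in distant}
        if len(sides) > 1:
            return PofoCall(target, "NA", 0.5, "MT", False, undetermined=True,
                            reason="conflicting mtDNA predictions")
    parent, prob = _h0_parent(best)
    return PofoCall(target, parent, prob, best.predictor,
                    prob >= HIGH_CONFIDENCE)


@dataclass
class PofoEncoding:
    ds_mat: np.ndarray
    ds_pat: np.ndarray
    ds_dip: np.ndarray
    gp_mat: np.ndarray      # (n, 3) triplets
    gp_pat: np.ndarray
    gp_diff: np.ndarray     # (n, 3); NaN rows at homozygous sites


def encode_pofo(
    ap_mat: np.ndarray, ap_pat: np.ndarray, p_t: float
) -> PofoEncoding:
    """Probability-weighted parental dosages and GP triplets.

    ``ap_mat`` / ``ap_pat`` are haploid allele dosages in [0, 1] for the
    haplotypes labelled maternal/paternal; ``p_t`` in [0.5, 1] is the
    probability the labelling is correct.  ``GP_diff`` is defined at
    heterozygous sites only (rounded haploid dosages differ) and is missing
    where the diploid dosage vanishes.
    """
    ap_mat = np.asarray(ap_mat, dtype=float)
    ap_pat = np.asarray(ap_pat, dtype=float)
    if np.any((ap_mat < 0) | (ap_mat > 1) | (ap_pat < 0) | (ap_pat > 1)):
        raise ValueError("AP dosages must lie in [0, 1]")
    if not 0.5 <= p_t <= 1.0:
        raise ValueError("p_t must lie in [0.5, 1]")
    ds_mat = ap_mat * p_t + ap_pat * (1.0 - p_t)
    ds_pat = ap_pat * p_t + ap_mat * (1.0 - p_t)
    ds_dip = ds_mat + ds_pat
    gp_mat = np.stack([1.0 - ds_mat, ds_mat, np.zeros_like(ds_mat)], axis=-1)
    gp_pat = np.stack([1.0 - ds_pat, ds_pat, np.zeros_like(ds_pat)], axis=-1)
    het = (np.round(ap_mat) != np.round(ap_pat)) & (ds_dip > 0)
    gp_diff = np.full(gp_mat.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        gp_diff[het, 0] = ds_mat[het] / ds_dip[het]
        gp_diff[het, 1] = ds_pat[het] / ds_dip[het]
        gp_diff[het, 2] = 0.0
    return PofoEncoding(ds_mat, ds_pat, ds_dip, gp_mat, gp_pat, gp_diff)


def filter_variants(
    info_scores: np.ndarray,
    freqs: np.ndarray,
    ds_mat: np.ndarray | None = None,
    ds_pat: np.ndarray | None = None,
    info_min: float = 0.8,
    maf_min: float = 0.01,
    dosage_certainty: float = 0.99,
) -> dict:
    """Variant and entry inclusion masks for the association scans.

    The scan mask keeps variants with imputation INFO > 0.8 and minor
    allele frequency > 1%.  The differential scan additionally requires,
    per individual and variant, one parental dosage above 0.99 and the
    other below 1 - 0.99 (a near-certain heterozygote assignment).
    """
    info_scores = np.asarray(info_scores, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    maf = np.minimum(freqs, 1.0 - freqs)
    scan = (info_scores > info_min) & (maf > maf_min)
    out = {"scan": scan}
    if ds_mat is not None and ds_pat is not None:
        hi = np.maximum(ds_mat, ds_pat)
        lo = np.minimum(ds_mat, ds_pat)
        out["diff_entries"] = (hi > dosage_certainty) & (lo < 1 - dosage_certainty)
    return out
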