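"""Calibrated parental-side probabilities from X sharing and mtDNA MVS.

Both predictors use the same empirical estimator: given training values for
targets with known paternal- and maternal-side relatives, the probability
that an observed value ``v`` comes from the paternal side is the ratio of
empirical class CDFs

    Pr(pat | value < v) = F_pat(v) / (F_pat(v) + F_mat(v))

evaluated with strict "<" below a separation-maximising cut, and the
symmetric ">" (survival-function) form above it for the maternal side.
X sharing lengths are small for paternal relatives (fathers transmit no X
to sons) and large for maternal ones; mtDNA minor-variant sharing (MVS) is
high for maternal-line relatives, so both predictors share the orientation
low -> paternal, high -> maternal, which is auto-detected from the
calibration class means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "mvs",
    "CalibrationTable",
    "ParentSidePrediction",
    "prob_side_x",
    "prob_side_mvs",
    "accuracy_at_threshold",
]


def mvs(v_t: np.ndarray, v_r: np.ndarray) -> float:
    """Minor variant sharing: fraction of mtDNA sites where both individuals
    carry the minor allele, ``v_t . v_r / M``."""
    a = np.asarray(v_t)
    b = np.asarray(v_r)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("minor-allele vectors must be equal-length 1-D")
    if a.size == 0:
        raise ValueError("MVS undefined for zero mtDNA variants")
    return float(a @ b) / a.size


@dataclass
class ParentSidePrediction:
    target: object
    group: object
    predictor: str          # X / MT / SIB / PED
    value: float
    side: str               # 'pat' or 'mat'
    probability: float      # in [0.5, 1]
    degree: int | None = None

    @property
    def pr_pat(self) -> float:
        return self.probability if self.side == "pat" else 1.0 - self.probability

    @property
    def pr_mat(self) -> float:
        return 1.0 - self.pr_pat


class CalibrationTable:
    """Training observations (value, truth side, stratum) for the empirical
    side-probability estimator."""

    def __init__(self, frame: pd.DataFrame | None = None):
        cols = ["value", "side", "stratum"]
        if frame is None:
            frame = pd.DataFrame(columns=cols)
        self.frame = frame[cols].reset_index(drop=True)
        if not np.isfinite(self.frame["value"]).all():
            raise ValueError("calibration values must be finite")

    def add(self, value: float, side: str, stratum: str) -> None:
        self.frame.loc[len(self.frame)] = [float(value), side, stratum]

    def stratum_values(self, stratum: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.frame[self.frame["stratum"] == stratum]
        pat = sub.loc[sub["side"] == "pat", "value"].to_numpy(dtype=float)
        mat = sub.loc[sub["side"] == "mat", "value"].to_numpy(dtype=float)
        return pat, mat

    def has_stratum(self, stratum: str) -> bool:
        pat, mat = self.stratum_values(stratum)
        return len(pat) > 0 and len(mat) > 0

    def without(self, target_values: tuple[float, ...], stratum: str
                ) -> "CalibrationTable":
        """Leave-one-out copy: drop one row per matching (value, stratum)."""
        frame = self.frame.copy()
        for v in target_values:
            hit = frame[(frame["stratum"] == stratum)
                        & np.isclose(frame["value"], v)].index
            if len(hit):
                frame = frame.drop(hit[0])
        return CalibrationTable(frame)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.frame.to_dict(orient="list"), fh)

    @classmethod
    def from_json(cls, path) -> "CalibrationTable":
        with open(path) as fh:
            return cls(pd.DataFrame(json.load(fh)))


# --------------------------------------------------------------------------- #
def _separation_cut(low: np.ndarray, high: np.ndarray) -> float:
    """Midpoint of the training-value interval maximising class separation
    (Youden-style: fraction of low-class below + fraction of high-class
    above the cut)."""
    values = np.unique(np.concatenate([low, high]))
    candidates = np.concatenate(
        [[values[0] - 1.0], 0.5 * (values[1:] + values[:-1]), [values[-1] + 1.0]]
    )
    lo = np.sort(low)
    hi = np.sort(high)
    score = (np.searchsorted(lo, candidates, side="left") / len(lo)
             + 1.0 - np.searchsorted(hi, candidates, side="right") / len(hi))
    best = np.flatnonzero(score >= score.max() - 1e-12)
    return float(0.5 * (candidates[best[0]] + candidates[best[-1]]))


def empirical_side_probability(
    value: float, pat_values: np.ndarray, mat_values: np.ndarray,
    orientation: str = "auto",
) -> tuple[str, float]:
    """(side, probability) from the two-sided empirical-ratio estimator.

    With ``orientation='auto'`` the class whose training mean is smaller
    plays the "low" role (which makes the result exactly symmetric under a
    label swap); ``'pat_low'`` fixes the paternal class as the low-value
    one, for predictors whose sign convention is known a priori.  Strict
    inequalities are used throughout, matching the indicator definitions.
    """
    pat_values = np.asarray(pat_values, dtype=float)
    mat_values = np.asarray(mat_values, dtype=float)
    if len(pat_values) == 0 or len(mat_values) == 0:
        raise ValueError("calibration requires both truth classes")
    if orientation == "pat_low" or (
        orientation == "auto" and pat_values.mean() <= mat_values.mean()
    ):
        low, high = pat_values, mat_values
        low_side, high_side = "pat", "mat"
    elif orientation == "auto":
        low, high = mat_values, pat_values
        low_side, high_side = "mat", "pat"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    cut = _separation_cut(low, high)
    if value < cut:
        f_low = np.mean(low < value)
        f_high = np.mean(high < value)
        if f_low + f_high == 0:
            if np.sum(low <= value) + np.sum(high <= value) == 0:
                pr_low = 1.0  # beyond every training value on the low side
            else:
                # ties at the value (e.g. a detection floor): inclusive
                # counts with a half pseudo-count keep ties informative
                # without claiming certainty
                f_low = (np.sum(low <= value) + 0.5) / (len(low) + 1)
                f_high = (np.sum(high <= value) + 0.5) / (len(high) + 1)
                pr_low = f_low / (f_low + f_high)
        else:
            pr_low = f_low / (f_low + f_high)
    else:
        g_low = np.mean(low > value)
        g_high = np.mean(high > value)
        if g_low + g_high == 0:
            if np.sum(low >= value) + np.sum(high >= value) == 0:
                pr_low = 0.0  # beyond every training value on the high side
            else:
                g_low = (np.sum(low >= value) + 0.5) / (len(low) + 1)
                g_high = (np.sum(high >= value) + 0.5) / (len(high) + 1)
                pr_low = 1.0 - g_high / (g_low + g_high)
        else:
            pr_low = 1.0 - g_high / (g_low + g_high)
    if pr_low >= 0.5:
        return low_side, float(pr_low)
    return high_side, float(1.0 - pr_low)


def prob_side_x(
    l: float, calibration: CalibrationTable, stratum: str = "X",
    target=None, group=None,
) -> ParentSidePrediction:
    """Parental side of a surrogate-parent group from its largest X-sharing
    length ``l`` (cM).  Short sharing favours the paternal side, long
    sharing the maternal side."""
    if l < 0:
        raise ValueError("sharing length must be non-negative")
    pat, mat = calibration.stratum_values(stratum)
    if len(pat) == 0 or len(mat) == 0:
        raise ValueError("degenerate calibration: one class empty")
    side, prob = empirical_side_probability(l, pat, mat)
    return ParentSidePrediction(target, group, "X", float(l), side, prob)


def prob_side_mvs(
    mvs_value: float, degree: int, calibration: CalibrationTable,
    target=None, group=None,
) -> ParentSidePrediction | None:
    """Parental side from mtDNA minor-variant sharing, within the stratum of
    the relative's degree.  Returns None when no calibration stratum exists
    for that degree (prediction withheld)."""
    stratum = f"MT{degree}"
    if not calibration.has_stratum(stratum):
        return None
    pat, mat = calibration.stratum_values(stratum)
    side, prob = empirical_side_probability(float(mvs_value), pat, mat)
    return ParentSidePrediction(target, group, "MT", float(mvs_value), side,
                                prob, degree=degree)


def accuracy_at_threshold(
    predictions: pd.DataFrame, truth: pd.DataFrame | dict, p: float
) -> float:
    """TP / (TP + FP) over calls with probability > p.

    ``predictions`` needs columns ``target``, ``side``, ``probability``;
    ``truth`` maps target -> truth side.  Raises when no call clears p.
    """
    if isinstance(truth, pd.DataFrame):
        truth = dict(zip(truth["target"], truth["side"]))
    confident = predictions[predictions["probability"] > p]
    if len(confident) == 0:
        raise ValueError(f"no calls with probability > {p}")
    correct = np.array(
        [row["side"] == truth[row["target"]] for _, row in confident.iterrows()]
    )
    return float(correct.mean())
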