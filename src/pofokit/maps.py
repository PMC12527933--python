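"""Sex-specific genetic maps.

A :class:`GeneticMap` stores, per chromosome, an ordered table of
``(pos, cm_female, cm_male)`` rows.  Genetic positions between rows are
linear in physical position, which makes centimorgan lookup a plain
piecewise-linear interpolation.  Map lengths are exposed in Morgans per sex
and sex-averaged, since the expected number of crossovers per meiosis equals
the sex-specific map length in Morgans.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "HUMAN_AUTOSOME_LENGTHS"]

#: Approximate genetic lengths (cM) of human autosomes 1..22.  Female maps
#: total ~43 Morgans and male maps ~26 Morgans, with per-chromosome weights
#: proportional to pedigree-based map lengths.
_CHROM_WEIGHTS = np.array(
    [0.0786, 0.0724, 0.0610, 0.0577, 0.0559, 0.0527, 0.0506, 0.0474,
     0.0450, 0.0465, 0.0437, 0.0467, 0.0365, 0.0340, 0.0351, 0.0367,
     0.0366, 0.0340, 0.0308, 0.0290, 0.0184, 0.0197]
)
_CHROM_WEIGHTS = _CHROM_WEIGHTS / _CHROM_WEIGHTS.sum()

HUMAN_AUTOSOME_LENGTHS: dict[str, tuple[float, float]] = {
    str(c + 1): (float(w * 4300.0), float(w * 2600.0))
    for c, w in enumerate(_CHROM_WEIGHTS)
}
"""chrom -> (female cM, male cM); totals ~43 and ~26 Morgans."""


class GeneticMap:
    """Per-chromosome bp <-> sex-specific cM lookup tables.

    Parameters
    ----------
    tables
        Mapping from chromosome name to a DataFrame with columns
        ``pos`` (bp, strictly increasing), ``cm_female`` and ``cm_male``
        (both non-decreasing).
    """

    def __init__(self, tables: Mapping[str, pd.DataFrame]):
        self._tables: dict[str, pd.DataFrame] = {}
        for chrom, tab in tables.items():
            tab = tab.reset_index(drop=True)
            pos = tab["pos"].to_numpy()
            if len(tab) == 0:
                raise ValueError(f"empty map for chromosome {chrom}")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            for col in ("cm_female", "cm_male"):
                if np.any(np.diff(tab[col].to_numpy()) < -1e-12):
                    raise ValueError(f"{col} decreasing on {chrom}")
            self._tables[chrom] = tab[["pos", "cm_female", "cm_male"]].copy()

    @property
    def chromosomes(self) -> list[str]:
        return list(self._tables)

    def table(self, chrom: str) -> pd.DataFrame:
        try:
            return self._tables[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    # ------------------------------------------------------------------ #
    def interpolate(self, chrom: str, bp, sex: str | None = None):
        """cM position(s) at physical coordinate(s) ``bp``.

        ``sex`` is ``'female'``, ``'male'``, ``'avg'`` or None; None returns
        a ``(cm_female, cm_male)`` tuple.  Coordinates outside the map range
        are clamped to the ends.
        """
        tab = self.table(chrom)
        pos = tab["pos"].to_numpy(dtype=float)
        f = np.interp(bp, pos, tab["cm_female"].to_numpy(dtype=float))
        m = np.interp(bp, pos, tab["cm_male"].to_numpy(dtype=float))
        if sex is None:
            return f, m
        if sex == "female":
            return f
        if sex == "male":
            return m
        if sex == "avg":
            return 0.5 * (f + m)
        raise ValueError(f"unknown sex {sex!r}")

    def bp_at_cm(self, chrom: str, cm, sex: str) -> np.ndarray:
        """Inverse lookup: physical position at genetic position ``cm``."""
        tab = self.table(chrom)
        if sex == "female":
            grid = tab["cm_female"].to_numpy(dtype=float)
        elif sex == "male":
            grid = tab["cm_male"].to_numpy(dtype=float)
        elif sex == "avg":
            grid = 0.5 * (tab["cm_female"] + tab["cm_male"]).to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown sex {sex!r}")
        # np.interp needs strictly increasing xp; collapse plateaus
        pos = tab["pos"].to_numpy(dtype=float)
        keep = np.concatenate([[True], np.diff(grid) > 0])
        return np.interp(cm, grid[keep], pos[keep])

    def length_cm(self, chrom: str, sex: str = "avg") -> float:
        tab = self.table(chrom)
        f = float(tab["cm_female"].iloc[-1] - tab["cm_female"].iloc[0])
        m = float(tab["cm_male"].iloc[-1] - tab["cm_male"].iloc[0])
        if sex == "female":
            return f
        if sex == "male":
            return m
        if sex == "avg":
            return 0.5 * (f + m)
        raise ValueError(f"unknown sex {sex!r}")

    def length_morgans(self, chrom: str, sex: str = "avg") -> float:
        return self.length_cm(chrom, sex) / 100.0

    def span_bp(self, chrom: str) -> tuple[int, int]:
        tab = self.table(chrom)
        return int(tab["pos"].iloc[0]), int(tab["pos"].iloc[-1])

    # ------------------------------------------------------------------ #
    @classmethod
    def uniform(cls, lengths: Mapping[str, tuple[int, float, float]]) -> "GeneticMap":
        """Constant-rate maps: chrom -> (bp_length, cm_female, cm_male)."""
        tables = {}
        for chrom, (bp_len, cm_f, cm_m) in lengths.items():
            tables[chrom] = pd.DataFrame(
                {"pos": [0, bp_len], "cm_female": [0.0, cm_f], "cm_male": [0.0, cm_m]}
            )
        return cls(tables)

    @classmethod
    def random(
        cls,
        lengths: Mapping[str, tuple[int, float, float]],
        n_intervals: int = 200,
        rate_shape: float = 1.0,
        rng: np.random.Generator | None = None,
    ) -> "GeneticMap":
        """Piecewise-linear maps with locally varying female/male rates.

        Interval rate multipliers are drawn independently per sex from a
        Gamma(``rate_shape``) distribution and renormalised so each
        chromosome reaches its target total length.  Independent draws give
        local female/male rate ratios spanning orders of magnitude, the
        feature the crossover sex-scoring exploits.
        """
        rng = np.random.default_rng() if rng is None else rng
        tables = {}
        for chrom, (bp_len, cm_f, cm_m) in lengths.items():
            pos = np.linspace(0, bp_len, n_intervals + 1).astype(np.int64)
            pos = np.unique(pos)
            k = len(pos) - 1
            inc_f = rng.gamma(rate_shape, 1.0, size=k)
            inc_m = rng.gamma(rate_shape, 1.0, size=k)
            # avoid true plateaus so the map remains invertible
            inc_f = np.maximum(inc_f, 1e-4)
            inc_m = np.maximum(inc_m, 1e-4)
            cmf = np.concatenate([[0.0], np.cumsum(inc_f)])
            cmm = np.concatenate([[0.0], np.cumsum(inc_m)])
            cmf *= cm_f / cmf[-1]
            cmm *= cm_m / cmm[-1]
            tables[chrom] = pd.DataFrame(
                {"pos": pos, "cm_female": cmf, "cm_male": cmm}
            )
        return cls(tables)

    # ------------------------------------------------------------------ #
    def to_tsv(self, path) -> None:
        """Write the 4-column ``pos chr cM_female cM_male`` format."""
        frames = []
        for chrom, tab in self._tables.items():
            out = pd.DataFrame(
                {
                    "pos": tab["pos"],
                    "chr": chrom,
                    "cM_female": tab["cm_female"],
                    "cM_male": tab["cm_male"],
                }
            )
            frames.append(out)
        pd.concat(frames).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", dtype={"chr": str})
        tables = {}
        for chrom, sub in df.groupby("chr", sort=False):
            tables[chrom] = pd.DataFrame(
                {
                    "pos": sub["pos"].to_numpy(),
                    "cm_female": sub["cM_female"].to_numpy(),
                    "cm_male": sub["cM_male"].to_numpy(),
                }
            )
        return cls(tables)
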