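"""Synthetic cohort simulator with full inheritance ground truth.

Generates pedigrees (trios, duos, sibling pairs, and 2nd/3rd/4th-degree
surrogate-relative families), transmits autosomal haplotypes through
sex-specific genetic maps with a Poisson crossover model (no interference),
and tracks X-chromosome and mitochondrial inheritance.  Every meiosis records
its crossover positions and every haplotype its parental origin, so each
downstream inference stage can be scored against truth.

Observed data are produced by corrupting the truth: per-chromosome random
haplotype orientation (interchromosomal phase is unknown to real phasing),
Poisson switch errors along each chromosome, and random genotype flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .maps import GeneticMap, HUMAN_AUTOSOME_LENGTHS

__all__ = [
    "SimConfig",
    "SimCohort",
    "simulate_meiosis",
    "simulate_cohort",
    "corrupt",
    "simulate_phenotypes",
    "default_autosome_spec",
]

MALE, FEMALE = 1, 2

#: Family types the generator knows how to build.  Values are the truth
#: relationship of the genotyped relative(s) to the target.
FAMILY_TYPES = ("trio", "duo", "sib", "sib2", "deg2", "deg3", "deg4",
                "deg2_both", "deg3_both", "deg4_both")


def default_autosome_spec(
    chromosomes: Sequence[str] | None = None, bp_per_cm: float = 6e5
) -> dict[str, tuple[int, float, float]]:
    """chrom -> (bp length, female cM, male cM) for realistic autosomes."""
    chroms = list(chromosomes) if chromosomes else list(HUMAN_AUTOSOME_LENGTHS)
    spec = {}
    for c in chroms:
        cm_f, cm_m = HUMAN_AUTOSOME_LENGTHS[c]
        spec[c] = (int(cm_f * bp_per_cm), cm_f, cm_m)
    return spec


@dataclass
class SimConfig:
    """Study conditions for :func:`simulate_cohort`.

    ``family_menu`` maps family type to its proportion (must sum to 1).
    Allele frequencies are drawn per site from a Beta distribution clipped
    away from fixation; mtDNA minor-allele frequencies use their own, more
    skewed spectrum.  ``switch_error_rate`` is expected switch errors per cM.
    """

    n_families: int = 100
    family_menu: Mapping[str, float] = field(
        default_factory=lambda: {
            "trio": 0.10, "duo": 0.10, "sib": 0.05, "sib2": 0.15,
            "deg2": 0.10, "deg2_both": 0.10, "deg3": 0.10,
            "deg3_both": 0.10, "deg4": 0.10, "deg4_both": 0.10,
        }
    )
    chromosomes: Sequence[str] = field(
        default_factory=lambda: list(HUMAN_AUTOSOME_LENGTHS)
    )
    n_variants: int = 400
    variants_per_cm: float | None = None  # overrides n_variants when set
    allele_freq_beta: tuple[float, float] = (0.8, 0.8)
    allele_freq_clip: tuple[float, float] = (0.02, 0.98)
    genotype_error_rate: float = 0.001
    switch_error_rate: float = 0.01
    map_intervals: int = 150
    map_rate_shape: float = 1.0
    x_n_variants: int = 600
    x_length_cm: float = 180.0
    x_length_bp: int = 150_000_000
    mt_n_variants: int = 400
    mt_mutation_rate: float = 0.002
    mt_freq_beta: tuple[float, float] = (0.5, 5.0)
    track_ancestry: bool = False  # founder-haplotype painting (truth IBD)
    seed: int = 0

    def validate(self) -> None:
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")
        props = np.array(list(self.family_menu.values()), dtype=float)
        if np.any(props < 0) or not np.isclose(props.sum(), 1.0):
            raise ValueError("family_menu proportions must be >=0 and sum to 1")
        for t in self.family_menu:
            if t not in FAMILY_TYPES:
                raise ValueError(f"unknown family type {t!r}")
        for r in (self.genotype_error_rate, self.switch_error_rate):
            if not 0 <= r < 1:
                raise ValueError("error rates must be in [0, 1)")
        if not 0 <= self.mt_mutation_rate < 1:
            raise ValueError("mt_mutation_rate must be in [0, 1)")


# --------------------------------------------------------------------------- #
# meiosis
# --------------------------------------------------------------------------- #
def _meiosis_indices(
    sex: int,
    gmap: GeneticMap,
    chrom: str,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Which parental haplotype (0/1) each site comes from, plus crossover
    positions (bp, strictly increasing)."""
    sex_name = "female" if sex == FEMALE else "male"
    length_cm = gmap.length_cm(chrom, sex_name)
    n_xo = int(rng.poisson(length_cm / 100.0)) if length_cm > 0 else 0
    tab = gmap.table(chrom)
    cm0 = float(tab["cm_female" if sex == FEMALE else "cm_male"].iloc[0])
    if n_xo:
        cms = np.sort(rng.uniform(cm0, cm0 + length_cm, size=n_xo))
        xo_bp = np.unique(np.asarray(gmap.bp_at_cm(chrom, cms, sex_name)))
    else:
        xo_bp = np.empty(0)
    start = int(rng.integers(2))
    hap_idx = (start + np.searchsorted(xo_bp, positions, side="right")) % 2
    return hap_idx, xo_bp


def simulate_meiosis(
    parent_haplotypes: np.ndarray,
    sex: int,
    gmap: GeneticMap,
    chrom: str,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a parent's pair of haplotypes.

    The crossover count is Poisson with mean equal to the parent-sex map
    length in Morgans; crossover positions are uniform on the sex-specific
    cM scale and mapped back to bp.  The gamete alternates between the two
    parental haplotypes at each crossover, starting from a random one.

    Returns ``(gamete, crossover_bp)`` with strictly increasing positions.
    """
    if parent_haplotypes.ndim != 2 or parent_haplotypes.shape[0] != 2:
        raise ValueError("parent_haplotypes must have shape (2, n_sites)")
    if parent_haplotypes.shape[1] != len(positions):
        raise ValueError("haplotypes and positions disagree")
    hap_idx, xo_bp = _meiosis_indices(sex, gmap, chrom, positions, rng)
    gamete = parent_haplotypes[hap_idx, np.arange(len(positions))]
    return gamete.astype(np.int8), xo_bp


# --------------------------------------------------------------------------- #
# cohort container
# --------------------------------------------------------------------------- #
class SimCohort:
    """Simulated cohort: truth and observed genomes plus metadata.

    Truth autosomal haplotypes are PofO-ordered: index 0 is paternal,
    index 1 maternal.  Observed haplotypes start as corrupted copies with
    per-chromosome random orientation.  Male X is stored at haplotype
    index 1 (maternal); index 0 is the ``-1`` sentinel.
    """

    def __init__(
        self,
        meta: pd.DataFrame,
        positions: dict[str, np.ndarray],
        afreq: dict[str, np.ndarray],
        truth: dict[str, np.ndarray],
        x_positions: np.ndarray,
        x_truth: np.ndarray,
        mt: np.ndarray,
        crossovers: pd.DataFrame,
        gmap: GeneticMap,
        config: SimConfig,
        ancestry: dict[str, np.ndarray] | None = None,
    ):
        self.meta = meta.reset_index(drop=True)
        self.positions = positions
        self.afreq = afreq
        self.truth = truth
        self.obs: dict[str, np.ndarray] = {c: h.copy() for c, h in truth.items()}
        self.x_positions = x_positions
        self.x_truth = x_truth
        self.mt = mt
        self.crossovers = crossovers
        self.gmap = gmap
        self.config = config
        self.ancestry = ancestry  # chrom -> (n_ind, 2, n_sites) founder labels
        self._index = {iid: i for i, iid in enumerate(self.meta["iid"])}

    # -- accessors ------------------------------------------------------- #
    @property
    def iids(self) -> list[str]:
        return list(self.meta["iid"])

    @property
    def chromosomes(self) -> list[str]:
        return list(self.truth)

    def index(self, iid: str) -> int:
        return self._index[iid]

    def sex(self, iid: str) -> int:
        return int(self.meta.loc[self.index(iid), "sex"])

    def haplotypes(self, iid: str, chrom: str, which: str = "obs") -> np.ndarray:
        store = self.obs if which == "obs" else self.truth
        return store[chrom][self.index(iid)]

    def genotypes(self, chrom: str, which: str = "obs") -> np.ndarray:
        """(n_individuals, n_sites) diploid 0/1/2 matrix."""
        store = self.obs if which == "obs" else self.truth
        return store[chrom].sum(axis=1, dtype=np.int8)

    def x_haplotypes(self, iid: str) -> np.ndarray:
        """Male: single maternal X, shape (1, nx).  Female: shape (2, nx)."""
        row = self.x_truth[self.index(iid)]
        if self.sex(iid) == MALE:
            return row[1:2]
        return row

    def mt_vector(self, iid: str) -> np.ndarray:
        return self.mt[self.index(iid)]

    def genotyped_iids(self) -> list[str]:
        return list(self.meta.loc[self.meta["genotyped"], "iid"])

    def targets(self) -> list[str]:
        return list(self.meta.loc[self.meta["role"] == "target", "iid"])


# --------------------------------------------------------------------------- #
# cohort generation
# --------------------------------------------------------------------------- #
def _draw_positions(rng: np.random.Generator, lo: int, hi: int, n: int) -> np.ndarray:
    """n distinct sorted integer positions in [lo, hi)."""
    pos = np.unique(rng.integers(lo, hi, size=2 * n + 16, dtype=np.int64))
    while len(pos) < n:  # pragma: no cover - astronomically unlikely
        pos = np.unique(
            np.concatenate([pos, rng.integers(lo, hi, size=n, dtype=np.int64)])
        )
    return np.sort(rng.choice(pos, size=n, replace=False))


class _Builder:
    def __init__(self, cfg: SimConfig, gmap: GeneticMap, rng: np.random.Generator):
        self.cfg = cfg
        self.gmap = gmap
        self.rng = rng
        self.positions: dict[str, np.ndarray] = {}
        self.afreq: dict[str, np.ndarray] = {}
        for chrom in cfg.chromosomes:
            lo, hi = gmap.span_bp(chrom)
            if cfg.variants_per_cm is not None:
                nv = max(10, int(gmap.length_cm(chrom, "avg")
                                 * cfg.variants_per_cm))
            else:
                nv = cfg.n_variants
            self.positions[chrom] = _draw_positions(rng, lo + 1, hi, nv)
            self.afreq[chrom] = np.clip(
                rng.beta(*cfg.allele_freq_beta, size=nv),
                *cfg.allele_freq_clip,
            )
        self.x_positions = _draw_positions(rng, 1, cfg.x_length_bp, cfg.x_n_variants)
        self.x_afreq = np.clip(
            rng.beta(*cfg.allele_freq_beta, size=cfg.x_n_variants),
            *cfg.allele_freq_clip,
        )
        self.mt_afreq = np.clip(
            rng.beta(*cfg.mt_freq_beta, size=cfg.mt_n_variants), 0.005, 0.45
        )
        self.xmap = GeneticMap.uniform(
            {"X": (cfg.x_length_bp, cfg.x_length_cm, 1e-6)}
        )
        self.rows: list[dict] = []
        self.haps: dict[str, list[np.ndarray]] = {c: [] for c in cfg.chromosomes}
        self.anc: dict[str, list[np.ndarray]] | None = (
            {c: [] for c in cfg.chromosomes} if cfg.track_ancestry else None
        )
        self.xhaps: list[np.ndarray] = []
        self.mt: list[np.ndarray] = []
        self.xo: list[tuple] = []
        self.counter = 0

    # ------------------------------------------------------------------ #
    def new_iid(self) -> str:
        self.counter += 1
        return f"I{self.counter:05d}"

    def founder(self, sex, gen, family, role, genotyped,
                rel_side=None, rel_degree=None) -> int:
        iid = self.new_iid()
        founder_no = len(self.rows)
        for chrom in self.cfg.chromosomes:
            p = self.afreq[chrom]
            h = (self.rng.random((2, len(p))) < p).astype(np.int8)
            self.haps[chrom].append(h)
            if self.anc is not None:
                lab = np.empty((2, len(p)), dtype=np.int32)
                lab[0] = 2 * founder_no
                lab[1] = 2 * founder_no + 1
                self.anc[chrom].append(lab)
        xa = (self.rng.random((2, len(self.x_afreq))) < self.x_afreq).astype(np.int8)
        if sex == MALE:
            xa[0] = -1  # single X, stored maternally at index 1
        self.xhaps.append(xa)
        self.mt.append(
            (self.rng.random(len(self.mt_afreq)) < self.mt_afreq).astype(np.int8)
        )
        self._add_row(iid, sex, gen, family, role, genotyped, None, None,
                      rel_side, rel_degree)
        return len(self.rows) - 1

    def child(self, fa: int, mo: int, sex, gen, family, role, genotyped,
              rel_side=None, rel_degree=None) -> int:
        iid = self.new_iid()
        cfg = self.cfg
        for chrom in cfg.chromosomes:
            pos = self.positions[chrom]
            ar = np.arange(len(pos))
            idx_p, xo_p = _meiosis_indices(MALE, self.gmap, chrom, pos,
                                           self.rng)
            idx_m, xo_m = _meiosis_indices(FEMALE, self.gmap, chrom, pos,
                                           self.rng)
            pat = self.haps[chrom][fa][idx_p, ar].astype(np.int8)
            mat = self.haps[chrom][mo][idx_m, ar].astype(np.int8)
            self.haps[chrom].append(np.stack([pat, mat]))
            if self.anc is not None:
                self.anc[chrom].append(np.stack([
                    self.anc[chrom][fa][idx_p, ar],
                    self.anc[chrom][mo][idx_m, ar],
                ]))
            for p in xo_p:
                self.xo.append((iid, chrom, "P", float(p)))
            for p in xo_m:
                self.xo.append((iid, chrom, "M", float(p)))
        # X: mother recombines her two Xs; father passes his X to daughters
        mo_x = self.xhaps[mo]
        mat_x, _ = simulate_meiosis(mo_x, FEMALE, self.xmap, "X",
                                    self.x_positions, self.rng)
        xa = np.empty((2, len(self.x_positions)), dtype=np.int8)
        xa[1] = mat_x
        if sex == MALE:
            xa[0] = -1
        else:
            xa[0] = self.xhaps[fa][1]  # father's single X
        self.xhaps.append(xa)
        # mtDNA: mother's vector plus rare per-site mutations
        mut = self.rng.random(len(self.mt_afreq)) < cfg.mt_mutation_rate
        self.mt.append((self.mt[mo] ^ mut).astype(np.int8))
        self._add_row(iid, sex, gen, family, role, genotyped,
                      self.rows[fa]["iid"], self.rows[mo]["iid"],
                      rel_side, rel_degree)
        return len(self.rows) - 1

    def _add_row(self, iid, sex, gen, family, role, genotyped,
                 father, mother, rel_side, rel_degree):
        age = 85.0 - 28.0 * gen + float(self.rng.normal(0, 3))
        self.rows.append(
            dict(iid=iid, sex=int(sex), age=round(age, 1), father=father,
                 mother=mother, family=family, role=role,
                 genotyped=bool(genotyped), rel_side=rel_side,
                 rel_degree=rel_degree, generation=gen)
        )

    def rand_sex(self) -> int:
        return MALE if self.rng.random() < 0.5 else FEMALE


def _opp(sex: int) -> int:
    return FEMALE if sex == MALE else MALE


def _side_lineage(b: _Builder, fam: str, degree: int, mid_sex: int) -> int:
    """One family side: grandparents, the target's (ungenotyped) parent of
    ``mid_sex``, and a genotyped relative of the requested degree on that
    side.  Returns the parent's index."""
    gf = b.founder(MALE, 0, fam, "grandparent", False)
    gm = b.founder(FEMALE, 0, fam, "grandparent", False)
    p = b.child(gf, gm, mid_sex, 1, fam, "parent", False)
    side = "pat" if mid_sex == MALE else "mat"
    if degree == 2:
        b.child(gf, gm, b.rand_sex(), 1, fam, "relative", True,
                rel_side=side, rel_degree=2)
        return p
    a_sex = b.rand_sex()
    a = b.child(gf, gm, a_sex, 1, fam, "aunt_uncle", False)
    sa = b.founder(_opp(a_sex), 1, fam, "spouse", False)
    a_fa, a_mo = (a, sa) if a_sex == MALE else (sa, a)
    c_sex = b.rand_sex()
    cz = b.child(a_fa, a_mo, c_sex, 2, fam, "cousin", degree == 3,
                 rel_side=side if degree == 3 else None,
                 rel_degree=3 if degree == 3 else None)
    if degree == 4:
        sc = b.founder(_opp(c_sex), 2, fam, "spouse", False)
        c_fa, c_mo = (cz, sc) if c_sex == MALE else (sc, cz)
        b.child(c_fa, c_mo, b.rand_sex(), 3, fam, "relative", True,
                rel_side=side, rel_degree=4)
    return p


def _build_family(b: _Builder, ftype: str, fam: str) -> None:
    rng = b.rng
    if ftype in ("trio", "duo"):
        fa = b.founder(MALE, 0, fam, "father", True)
        mo = b.founder(FEMALE, 0, fam, "mother", True)
        b.child(fa, mo, b.rand_sex(), 1, fam, "target", True)
        if ftype == "duo":
            drop = fa if rng.random() < 0.5 else mo
            b.rows[drop]["genotyped"] = False
            b.rows[drop]["role"] = "ungenotyped_parent"
    elif ftype == "sib":
        fa = b.founder(MALE, 0, fam, "parent", False)
        mo = b.founder(FEMALE, 0, fam, "parent", False)
        b.child(fa, mo, b.rand_sex(), 1, fam, "target", True)
        b.child(fa, mo, b.rand_sex(), 1, fam, "sibling", True,
                rel_degree=1)
    elif ftype == "sib2":
        # sibling pair plus one avuncular relative for scaffolding
        mid_sex = b.rand_sex()
        p = _side_lineage(b, fam, 2, mid_sex)
        q = b.founder(_opp(mid_sex), 1, fam, "parent", False)
        fa_i, mo_i = (p, q) if mid_sex == MALE else (q, p)
        b.child(fa_i, mo_i, b.rand_sex(), 2, fam, "target", True)
        b.child(fa_i, mo_i, b.rand_sex(), 2, fam, "sibling", True,
                rel_degree=1)
    elif ftype in ("deg2", "deg3", "deg4"):
        mid_sex = b.rand_sex()
        p = _side_lineage(b, fam, int(ftype[-1]), mid_sex)
        q = b.founder(_opp(mid_sex), 1, fam, "parent", False)
        fa_i, mo_i = (p, q) if mid_sex == MALE else (q, p)
        b.child(fa_i, mo_i, b.rand_sex(), 2, fam, "target", True)
    elif ftype in ("deg2_both", "deg3_both", "deg4_both"):
        # one relative of the stated degree on each parental side
        degree = int(ftype[3])
        fa_i = _side_lineage(b, fam, degree, MALE)
        mo_i = _side_lineage(b, fam, degree, FEMALE)
        b.child(fa_i, mo_i, b.rand_sex(), 2, fam, "target", True)
    else:  # pragma: no cover
        raise ValueError(f"unknown family type {ftype!r}")


def simulate_cohort(config: SimConfig, gmap: GeneticMap | None = None) -> SimCohort:
    """Realise a cohort from ``config``; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if gmap is None:
        spec = {
            c: (int(HUMAN_AUTOSOME_LENGTHS[c][0] * 6e5),) + HUMAN_AUTOSOME_LENGTHS[c]
            for c in config.chromosomes
        }
        gmap = GeneticMap.random(
            spec, n_intervals=config.map_intervals,
            rate_shape=config.map_rate_shape, rng=rng,
        )
    b = _Builder(config, gmap, rng)
    types = list(config.family_menu)
    props = np.array([config.family_menu[t] for t in types], dtype=float)
    counts = rng.multinomial(config.n_families, props / props.sum())
    fam_no = 0
    for ftype, cnt in zip(types, counts):
        for _ in range(cnt):
            fam_no += 1
            _build_family(b, ftype, f"F{fam_no:04d}")
    meta = pd.DataFrame(b.rows)
    truth = {c: np.stack(b.haps[c]) for c in config.chromosomes}
    cohort = SimCohort(
        meta=meta,
        positions=b.positions,
        afreq=b.afreq,
        truth=truth,
        x_positions=b.x_positions,
        x_truth=np.stack(b.xhaps),
        mt=np.stack(b.mt),
        crossovers=pd.DataFrame(b.xo, columns=["iid", "chrom", "parent", "pos"]),
        gmap=gmap,
        config=config,
        ancestry=({c: np.stack(b.anc[c]) for c in config.chromosomes}
                  if b.anc is not None else None),
    )
    corrupt(cohort, config.genotype_error_rate, config.switch_error_rate, rng)
    return cohort


# --------------------------------------------------------------------------- #
# corruption
# --------------------------------------------------------------------------- #
def corrupt(
    cohort: SimCohort,
    genotype_error_rate: float,
    switch_error_rate: float,
    rng: np.random.Generator,
) -> None:
    """Overwrite ``cohort.obs`` with corrupted copies of the truth.

    Each individual's haplotype pair gets, per chromosome: a random overall
    orientation (interchromosomal phase is unobserved), switch errors as a
    Poisson process with rate ``switch_error_rate`` per cM, and genotype
    errors flipping one allele at the given per-genotype rate.
    """
    if not (0 <= genotype_error_rate < 1 and 0 <= switch_error_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    n = len(cohort.meta)
    for chrom in cohort.chromosomes:
        haps = cohort.truth[chrom].copy()
        pos = cohort.positions[chrom]
        length_cm = cohort.gmap.length_cm(chrom, "avg")
        swap = rng.random(n) < 0.5
        for i in range(n):
            h = haps[i]
            if swap[i]:
                h = h[::-1]
            n_sw = rng.poisson(switch_error_rate * length_cm)
            if n_sw:
                lo, hi = cohort.gmap.span_bp(chrom)
                at = np.sort(rng.uniform(lo, hi, size=n_sw))
                parity = np.searchsorted(at, pos, side="right") % 2 == 1
                h = h.copy()
                h[:, parity] = h[::-1][:, parity]
            haps[i] = h
        if genotype_error_rate > 0:
            flips = rng.random(haps.shape) < genotype_error_rate / 2.0
            haps = np.where(flips, 1 - haps, haps).astype(np.int8)
        cohort.obs[chrom] = haps


# --------------------------------------------------------------------------- #
# phenotypes
# --------------------------------------------------------------------------- #
def simulate_phenotypes(
    cohort: SimCohort,
    effects: Sequence[Mapping],
    rng: np.random.Generator,
    kind: str = "quantitative",
    sex_effect: float = 0.0,
    age_effect: float = 0.0,
    noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Traits with parent-of-origin genetic architecture.

    ``effects`` entries are mappings with keys ``chrom``, ``index`` (variant
    column), ``beta_pat`` and ``beta_mat``.  The quantitative trait is the
    sum of parental-allele effects, covariate effects and Gaussian noise;
    binary traits pass the same linear predictor through a logistic link.
    """
    meta = cohort.meta
    eta = np.zeros(len(meta))
    for eff in effects:
        chrom, idx = eff["chrom"], int(eff["index"])
        if chrom not in cohort.truth or not 0 <= idx < len(cohort.positions[chrom]):
            raise KeyError(f"unknown causal variant {chrom}:{idx}")
        pat = cohort.truth[chrom][:, 0, idx].astype(float)
        mat = cohort.truth[chrom][:, 1, idx].astype(float)
        eta += eff["beta_pat"] * pat + eff["beta_mat"] * mat
    eta += sex_effect * (meta["sex"].to_numpy() - 1)
    eta += age_effect * (meta["age"].to_numpy() - meta["age"].mean())
    if kind == "quantitative":
        y = eta + rng.normal(0, noise_sd, size=len(meta))
    elif kind == "binary":
        p = 1.0 / (1.0 + np.exp(-(eta - eta.mean())))
        y = (rng.random(len(meta)) < p).astype(float)
    else:
        raise ValueError(f"unknown phenotype kind {kind!r}")
    return pd.DataFrame({"iid": meta["iid"], "phenotype": y})
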