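"""End-to-end parent-of-origin inference on a simulated cohort.

Chains the library stages the way a cohort analysis would: kinship and
relationship classification, surrogate-parent clustering, IBD anchoring and
scaffold phasing, X / mtDNA / sibling-crossover side prediction with
leave-one-out calibration, and predictor combination into final PofO calls.
Every step consumes only observed (corrupted) data; truth is touched solely
for calibration labels and for scoring the result.

Candidate relatives from the kinship classifier must share at least one
IBD segment (>= 3 cM) with the target to be used: a surrogate parent only
carries phasing information through IBD, and the requirement also screens
out spurious distant-kinship pairs at modest site counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import encode as enc
from . import ibdmap, interphase, parentside, relatedness, sibscore
from .maps import GeneticMap
from .simkit import MALE, SimCohort

__all__ = ["run_pipeline", "PipelineResult", "truth_encoding", "x_map"]


@dataclass
class PipelineResult:
    calls: pd.DataFrame
    predictions: list = field(default_factory=list)
    pair_table: pd.DataFrame | None = None

    def accuracy(self, min_probability: float = 0.0) -> float:
        ok = self.calls[
            (~self.calls["undetermined"])
            & (self.calls["p_t"] >= min_probability)
            & self.calls["truth_h0"].isin(["P", "M"])
        ]
        if len(ok) == 0:
            return float("nan")
        return float((ok["h0_parent"] == ok["truth_h0"]).mean())


def x_map(cohort: SimCohort) -> GeneticMap:
    """Uniform X genetic map matching the simulator's X configuration."""
    cfg = cohort.config
    return GeneticMap.uniform({"X": (cfg.x_length_bp, cfg.x_length_cm, 1e-6)})


# --------------------------------------------------------------------------- #
def _pair_classification(cohort: SimCohort) -> pd.DataFrame:
    iids = cohort.genotyped_iids()
    gmat = np.concatenate(
        [cohort.genotypes(c)[[cohort.index(i) for i in iids]]
         for c in cohort.chromosomes], axis=1,
    )
    pairs = relatedness.kinship_ibs(gmat, min_sites=min(1000, gmat.shape[1]))
    meta = cohort.meta.set_index("iid")
    ages = pd.DataFrame({"age": [meta.loc[i, "age"] for i in iids]})
    classified = relatedness.classify_pairs(pairs, ages)
    classified["iid_a"] = [iids[int(a)] for a in classified["a"]]
    classified["iid_b"] = [iids[int(b)] for b in classified["b"]]
    classified["parent_iid"] = [
        iids[int(p)] if p is not None and not (isinstance(p, float) and np.isnan(p))
        else None
        for p in classified["parent"]
    ]
    return classified


def _relationship_maps(classified: pd.DataFrame
                       ) -> tuple[dict, dict, dict]:
    """(relatives, siblings, parents): per-individual degree-2..4 relatives,
    the first classified sibling, and genotyped parents."""
    relatives: dict[str, dict[str, int]] = {}
    siblings: dict[str, str] = {}
    parents: dict[str, list[str]] = {}
    classified = classified[classified["relationship"] != "unrelated"]
    for _, r in classified.iterrows():
        rel = r["relationship"]
        a, b = r["iid_a"], r["iid_b"]
        if rel.startswith("degree"):
            deg = int(rel[-1])
            relatives.setdefault(a, {})[b] = deg
            relatives.setdefault(b, {})[a] = deg
        elif rel == "sibling":
            siblings.setdefault(a, b)
            siblings.setdefault(b, a)
        elif rel == "parent_offspring":
            parent = r["parent_iid"]
            offspring = b if parent == a else a
            parents.setdefault(offspring, []).append(parent)
    return relatives, siblings, parents


def _member_segments(cohort: SimCohort, target: str, member: str) -> list:
    segs = []
    for chrom in cohort.chromosomes:
        segs.extend(
            ibdmap.detect_ibd(
                cohort.haplotypes(target, chrom),
                {member: cohort.haplotypes(member, chrom)},
                cohort.positions[chrom], cohort.gmap, chrom, group="?",
            )
        )
    return segs


def _truth_h0_label(cohort: SimCohort, target: str,
                    haps: dict[str, np.ndarray]) -> str:
    """Majority-vote truth parent of haplotype 0 of an oriented pair."""
    truth = {c: cohort.haplotypes(target, c, which="truth")
             for c in cohort.chromosomes}
    metrics = interphase.phasing_metrics(haps, truth)
    labels = list(metrics.get("chromosome_labels", {}).values())
    if not labels:
        return "NA"
    return "P" if labels.count("P") >= labels.count("M") else "M"


def _group_truth_side(meta: pd.DataFrame, members) -> str | None:
    sides = {meta.loc[m, "rel_side"] for m in members} - {None}
    sides = {s for s in sides if isinstance(s, str)}
    return sides.pop() if len(sides) == 1 else None


def _flip(side: str) -> str:
    return "mat" if side == "pat" else "pat"


def _pedigree_call(cohort: SimCohort, target: str, parent_iids: list[str],
                   meta: pd.DataFrame
                   ) -> tuple[parentside.ParentSidePrediction, str]:
    """PofO from genotyped parents: transmission logic per chromosome.

    Returns the (certain) prediction that the pedigree-phased paternal
    haplotype is haplotype 0, plus the truth label of that haplotype for
    scoring (majority vote over resolvable heterozygous sites).
    """
    father = mother = None
    for p in parent_iids:
        if meta.loc[p, "sex"] == MALE:
            father = p
        else:
            mother = p
    ok = bad = 0
    for chrom in cohort.chromosomes:
        cg = cohort.haplotypes(target, chrom).sum(axis=0)
        fg = (cohort.haplotypes(father, chrom).sum(axis=0)
              if father else None)
        mg = (cohort.haplotypes(mother, chrom).sum(axis=0)
              if mother else None)
        hp, _, _ = interphase.pedigree_phase(cg, fg, mg)
        truth = cohort.haplotypes(target, chrom, which="truth")
        sites = (truth[0] != truth[1]) & (hp != -1)
        ok += int((hp[sites] == truth[0][sites]).sum())
        bad += int((hp[sites] != truth[0][sites]).sum())
    pred = parentside.ParentSidePrediction(target, None, "PED", np.nan,
                                           "pat", 1.0)
    return pred, ("P" if ok >= bad else "M")


# --------------------------------------------------------------------------- #
def run_pipeline(cohort: SimCohort) -> PipelineResult:
    """Infer every target's haplotype-0 parent from observed data.

    Calibration of the X, MVS and sib-score predictors is leave-one-out:
    each target is scored against reference values from all other targets,
    whose truth sides come from the recorded pedigree.
    """
    classified = _pair_classification(cohort)
    relatives, siblings, parents = _relationship_maps(classified)
    meta = cohort.meta.set_index("iid")
    targets = cohort.targets()
    xmap = x_map(cohort)
    kin_lookup: dict[tuple[str, str], float] = {}
    for a, b, k in zip(classified["iid_a"], classified["iid_b"],
                       classified["kinship"]):
        if np.isfinite(k) and k >= relatedness.KINSHIP_BINS[4][0]:
            kin_lookup[(a, b)] = k
            kin_lookup[(b, a)] = k

    groups: dict[str, relatedness.RelativeSet] = {}
    scaffolds: dict[str, interphase.ScaffoldResult] = {}
    anchor_segs: dict[str, list] = {}
    sib_pairs = {t: siblings[t] for t in targets if t in siblings}

    for t in targets:
        cand = relatives.get(t, {})
        seg_by_member = {}
        usable = {}
        for m, deg in cand.items():
            segs = _member_segments(cohort, t, m)
            if segs:
                seg_by_member[m] = segs
                usable[m] = deg
        if not usable:
            continue
        rs = relatedness.cluster_surrogate_parents(t, usable, kin_lookup)
        groups[t] = rs
        labeled = []
        for m, segs in seg_by_member.items():
            side = rs.side_of(m)
            if side is None:
                continue
            labeled.extend(dataclasses.replace(s, group=side) for s in segs)
        anchor_segs[t] = labeled
        observed = {c: cohort.haplotypes(t, c) for c in cohort.chromosomes}
        scaffolds[t] = interphase.scaffold_phase(observed, cohort.positions,
                                                 labeled)
    # siblings of targets inherit the target's surrogate side for anchoring
    for t, sib in sib_pairs.items():
        if t in groups and sib not in scaffolds:
            labeled = []
            for m in groups[t].g1 | groups[t].g2:
                side = groups[t].side_of(m)
                for s in _member_segments(cohort, sib, m):
                    labeled.append(dataclasses.replace(s, group=side))
            observed = {c: cohort.haplotypes(sib, c)
                        for c in cohort.chromosomes}
            scaffolds[sib] = interphase.scaffold_phase(
                observed, cohort.positions, labeled
            )

    # --- raw predictor values (per target x group) ------------------------ #
    x_values: dict[tuple[str, str], float] = {}
    mt_values: dict[tuple[str, str], list[tuple[str, int, float]]] = {}
    group_truth: dict[tuple[str, str], str] = {}
    for t, rs in groups.items():
        for gname, members in (("G1", rs.g1), ("G2", rs.g2)):
            if not members:
                continue
            key = (t, gname)
            truth_side = _group_truth_side(meta, members)
            if truth_side:
                group_truth[key] = truth_side
            if cohort.sex(t) == MALE:
                grp_x = {m: cohort.x_haplotypes(m) for m in members}
                x_values[key] = ibdmap.longest_x_share(
                    cohort.x_haplotypes(t), grp_x, cohort.x_positions, xmap
                )
            mt_values[key] = [
                (m, rs.degrees[m],
                 parentside.mvs(cohort.mt_vector(t), cohort.mt_vector(m)))
                for m in sorted(members)
            ]

    # --- sibling genome scores ------------------------------------------- #
    sib_scores: dict[str, tuple[float, float]] = {}
    for t, sib in sib_pairs.items():
        if t not in scaffolds or sib not in scaffolds:
            continue
        chrom_scores, length = [], 0.0
        for chrom in cohort.chromosomes:
            if not (scaffolds[t].anchored.get(chrom)
                    and scaffolds[sib].anchored.get(chrom)):
                continue
            segs = ibdmap.detect_ibd(
                scaffolds[t].haplotypes[chrom],
                {sib: scaffolds[sib].haplotypes[chrom]},
                cohort.positions[chrom], cohort.gmap, chrom,
            )
            calls = sibscore.infer_crossovers(
                segs, {chrom: cohort.positions[chrom]}
            )
            for call in calls:
                sibscore.delta(call, cohort.gmap)
            chrom_scores.append(sibscore.chrom_score(calls))
            length += cohort.gmap.length_morgans(chrom, "avg")
        if chrom_scores:
            sib_scores[t] = (sibscore.genome_score(chrom_scores), length)

    # --- leave-one-out calibration + prediction -------------------------- #
    calib_rows = []
    for (t, gname), side in group_truth.items():
        key = (t, gname)
        if key in x_values:
            calib_rows.append((t, x_values[key], side, "X"))
        for _, deg, v in mt_values.get(key, []):
            calib_rows.append((t, v, side, f"MT{deg}"))
    calib = pd.DataFrame(calib_rows,
                         columns=["target", "value", "side", "stratum"])

    predictions: dict[str, list[parentside.ParentSidePrediction]] = {
        t: [] for t in targets
    }
    for t in groups:
        sub = calib[calib["target"] != t]
        table = parentside.CalibrationTable(sub[["value", "side", "stratum"]])
        for gname in ("G1", "G2"):
            key = (t, gname)
            if key in x_values:
                try:
                    pred = parentside.prob_side_x(x_values[key], table,
                                                  target=t, group=gname)
                except ValueError:
                    pred = None
                if pred is not None:
                    if gname == "G2":   # express as a haplotype-0 statement
                        pred = dataclasses.replace(pred,
                                                   side=_flip(pred.side))
                    predictions[t].append(pred)
            for member, deg, v in mt_values.get(key, []):
                pred = parentside.prob_side_mvs(v, deg, table, target=t,
                                                group=gname)
                if pred is not None:
                    if gname == "G2":
                        pred = dataclasses.replace(pred,
                                                   side=_flip(pred.side))
                    predictions[t].append(pred)

    val_rows = [
        (t, s, l, group_truth[(t, "G1")])
        for t, (s, l) in sib_scores.items() if (t, "G1") in group_truth
    ]
    validation = pd.DataFrame(
        val_rows, columns=["target", "score", "length", "h0_parent"]
    )
    for t, (s_t, l_t) in sib_scores.items():
        val = validation[validation["target"] != t]
        if val.empty or val["h0_parent"].nunique() < 2:
            continue
        try:
            predictions[t].append(
                sibscore.prob_pofo_sib(s_t, l_t, val, target=t)
            )
        except ValueError:
            continue

    # --- parental genomes override everything ----------------------------- #
    ped_truth: dict[str, str] = {}
    for t in targets:
        if t in parents:
            pred, label = _pedigree_call(cohort, t, parents[t], meta)
            predictions[t].append(pred)
            ped_truth[t] = label

    # --- combine and score ------------------------------------------------ #
    rows = []
    for t in targets:
        preds = predictions.get(t, [])
        if not preds:
            continue
        call = enc.combine_predictors(preds, target=t)
        if call.predictor == "PED":
            truth_h0 = ped_truth[t]
        else:
            truth_h0 = ("NA" if t not in scaffolds else
                        _truth_h0_label(cohort, t, scaffolds[t].haplotypes))
        rows.append(
            dict(target=t, h0_parent=call.h0_parent, p_t=call.p_t,
                 predictor=call.predictor,
                 high_confidence=call.high_confidence,
                 undetermined=call.undetermined, truth_h0=truth_h0)
        )
    calls = pd.DataFrame(rows)
    return PipelineResult(
        calls=calls,
        predictions=[p for ps in predictions.values() for p in ps],
        pair_table=classified,
    )


# --------------------------------------------------------------------------- #
def sib_truth_scores(
    n_pairs: int,
    seed: int,
    chromosome_spec: dict[str, tuple[int, float, float]] | None = None,
    variants_per_cm: float = 12.0,
    min_cm: float = 3.0,
) -> pd.DataFrame:
    """Sibling crossover counts and genome scores on truth-phased haplotypes.

    Simulates ``n_pairs`` sibling-pair families, detects IBD between each
    pair's truth haplotypes (perfect interchromosomal phasing: haplotype 0
    is paternal for every individual), infers crossovers from segment
    breakends and scores them with the sex-specific maps.  Returns one row
    per pair: breakend count ``n_xo``, genome score ``S`` and the genomic
    length ``l`` (sex-averaged Morgans) analysed.
    """
    from .maps import GeneticMap
    from .simkit import SimConfig, simulate_cohort

    kwargs = dict(
        n_families=n_pairs,
        family_menu={"sib": 1.0},
        variants_per_cm=variants_per_cm,
        genotype_error_rate=0.0,
        switch_error_rate=0.0,
        seed=seed,
    )
    gmap = None
    if chromosome_spec is not None:
        kwargs["chromosomes"] = list(chromosome_spec)
        rng = np.random.default_rng(seed + 1)
        gmap = GeneticMap.random(chromosome_spec, rng=rng)
    cfg = SimConfig(**kwargs)
    cohort = simulate_cohort(cfg, gmap=gmap)
    meta = cohort.meta
    total_l = sum(cohort.gmap.length_morgans(c, "avg")
                  for c in cohort.chromosomes)
    rows = []
    for fam, sub in meta[meta["role"].isin(["target", "sibling"])
                         ].groupby("family"):
        pair = list(sub["iid"])
        if len(pair) != 2:
            continue
        t, sib = pair
        n_xo = 0
        chrom_scores = []
        for chrom in cohort.chromosomes:
            segs = ibdmap.detect_ibd(
                cohort.haplotypes(t, chrom, which="truth"),
                {sib: cohort.haplotypes(sib, chrom, which="truth")},
                cohort.positions[chrom], cohort.gmap, chrom, min_cm=min_cm,
            )
            calls = sibscore.infer_crossovers(
                segs, {chrom: cohort.positions[chrom]}, min_cm=min_cm
            )
            n_xo += len(calls)
            for call in calls:
                sibscore.delta(call, cohort.gmap)
            chrom_scores.append(sibscore.chrom_score(calls))
        rows.append((fam, t, n_xo, sibscore.genome_score(chrom_scores),
                     total_l))
    return pd.DataFrame(rows, columns=["family", "target", "n_xo", "S", "l"])


# --------------------------------------------------------------------------- #
def truth_encoding(cohort: SimCohort, chrom: str, p_t: float = 1.0,
                   ap_noise: float = 0.0,
                   rng: np.random.Generator | None = None):
    """PofO encoding built from truth parental alleles, emulating haploid
    imputation output: AP values are the truth alleles optionally perturbed
    by uniform noise of the given amplitude, then probability-weighted."""
    pat = cohort.truth[chrom][:, 0, :].astype(float)
    mat = cohort.truth[chrom][:, 1, :].astype(float)
    if ap_noise > 0:
        rng = np.random.default_rng() if rng is None else rng
        pat = np.clip(pat + rng.uniform(-ap_noise, ap_noise, pat.shape), 0, 1)
        mat = np.clip(mat + rng.uniform(-ap_noise, ap_noise, mat.shape), 0, 1)
    return enc.encode_pofo(mat, pat, p_t)
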