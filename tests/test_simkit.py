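import numpy as np
import pytest

from pofokit.maps import GeneticMap
from pofokit.simkit import (
    FEMALE,
    MALE,
    SimConfig,
    corrupt,
    simulate_cohort,
    simulate_meiosis,
    simulate_phenotypes,
)


def _uniform_map(cm_f, cm_m, bp=1_000_000):
    return GeneticMap.uniform({"1": (bp, cm_f, cm_m)})


class TestMeiosis:
    def test_zero_length_map_gives_whole_parental_haplotype(self, rng):
        gmap = _uniform_map(0.0, 0.0)
        pos = np.arange(0, 1_000_000, 1000)
        parent = np.stack([np.zeros(len(pos), np.int8),
                           np.ones(len(pos), np.int8)])
        gamete, xo = simulate_meiosis(parent, MALE, gmap, "1", pos, rng)
        assert len(xo) == 0
        assert len(np.unique(gamete)) == 1  # one parent haplotype verbatim

    def test_crossover_count_matches_poisson_mean(self, rng):
        """10,000 male meioses on a 2-Morgan male map average 2 crossovers."""
        gmap = _uniform_map(300.0, 200.0)
        pos = np.array([0, 500_000, 999_999])
        parent = np.stack([np.zeros(3, np.int8), np.ones(3, np.int8)])
        counts = [
            len(simulate_meiosis(parent, MALE, gmap, "1", pos, rng)[1])
            for _ in range(10_000)
        ]
        assert np.mean(counts) == pytest.approx(2.0, abs=3 * np.sqrt(2 / 1e4))

    def test_single_crossover_switches_haplotypes_at_breakpoint(self, rng):
        gmap = _uniform_map(100.0, 100.0, bp=1000)
        pos = np.arange(1000)
        parent = np.stack([np.zeros(1000, np.int8), np.ones(1000, np.int8)])
        # find a meiosis with exactly one crossover and check the mosaic
        for _ in range(200):
            gamete, xo = simulate_meiosis(parent, FEMALE, gmap, "1", pos, rng)
            if len(xo) == 1:
                cut = int(np.searchsorted(pos, xo[0], side="right"))
                assert len(np.unique(gamete[:cut])) == 1
                assert len(np.unique(gamete[cut:])) == 1
                assert gamete[0] != gamete[-1]
                return
        pytest.fail("no single-crossover meiosis observed")

    def test_rejects_malformed_parent(self, rng):
        gmap = _uniform_map(100.0, 100.0)
        with pytest.raises(ValueError):
            simulate_meiosis(np.zeros((3, 10), np.int8), MALE, gmap, "1",
                             np.arange(10), rng)


class TestCohort:
    def test_same_seed_reproduces_cohort_exactly(self):
        cfg = SimConfig(n_families=10, chromosomes=["22"], n_variants=200,
                        seed=3)
        a = simulate_cohort(cfg)
        b = simulate_cohort(SimConfig(n_families=10, chromosomes=["22"],
                                      n_variants=200, seed=3))
        assert a.meta.equals(b.meta)
        np.testing.assert_array_equal(a.truth["22"], b.truth["22"])
        np.testing.assert_array_equal(a.obs["22"], b.obs["22"])
        np.testing.assert_array_equal(a.mt, b.mt)

    def test_trio_truth_kinship_near_quarter(self, trio_cohort):
        """Parent-offspring kinship on truth genotypes is ~0.25."""
        from pofokit.relatedness import kinship_ibs

        co = trio_cohort
        meta = co.meta.set_index("iid")
        g = np.concatenate(
            [co.genotypes(c, which="truth") for c in co.chromosomes], axis=1
        )
        pairs = []
        for iid in co.targets():
            i = co.index(iid)
            pairs.append((co.index(meta.loc[iid, "father"]), i))
            pairs.append((co.index(meta.loc[iid, "mother"]), i))
        est = kinship_ibs(g, pairs)
        assert est["kinship"].mean() == pytest.approx(0.25, abs=0.02)
        assert est["ibs0"].mean() < 1e-3

    def test_avuncular_truth_kinship_near_eighth(self):
        from pofokit.relatedness import kinship_ibs

        cfg = SimConfig(n_families=25, family_menu={"deg2": 1.0},
                        chromosomes=["20", "21", "22"], variants_per_cm=12.0,
                        genotype_error_rate=0.0, switch_error_rate=0.0,
                        seed=9)
        co = simulate_cohort(cfg)
        meta = co.meta.set_index("iid")
        g = np.concatenate(
            [co.genotypes(c, which="truth") for c in co.chromosomes], axis=1
        )
        pairs = []
        for fam, sub in co.meta.groupby("family"):
            t = sub[sub["role"] == "target"]["iid"].iloc[0]
            r = sub[sub["role"] == "relative"]["iid"].iloc[0]
            pairs.append((co.index(t), co.index(r)))
        est = kinship_ibs(g, pairs)
        assert est["kinship"].mean() == pytest.approx(0.125, abs=0.03)

    def test_male_x_is_single_and_maternal(self, trio_cohort):
        co = trio_cohort
        meta = co.meta.set_index("iid")
        for iid in co.iids:
            haps = co.x_haplotypes(iid)
            if co.sex(iid) == MALE:
                assert haps.shape[0] == 1
                mo = meta.loc[iid, "mother"]
                if mo is not None:
                    mx = co.x_truth[co.index(mo)]
                    # recombinant mosaic of the mother's two X haplotypes
                    assert ((haps[0] == mx[0]) | (haps[0] == mx[1])).all()
            else:
                assert haps.shape[0] == 2

    def test_mtdna_follows_maternal_line(self, trio_cohort):
        co = trio_cohort
        meta = co.meta.set_index("iid")
        mut = co.config.mt_mutation_rate
        for iid in co.targets():
            mo, fa = meta.loc[iid, "mother"], meta.loc[iid, "father"]
            d_mat = (co.mt_vector(iid) != co.mt_vector(mo)).mean()
            assert d_mat < 10 * mut + 0.02
        # paternal mtDNA is unrelated: average distance far larger
        d_pat = np.mean(
            [
                (co.mt_vector(i) != co.mt_vector(meta.loc[i, "father"])).mean()
                for i in co.targets()
            ]
        )
        assert d_pat > 0.05

    def test_nonfounder_haplotype_is_single_parent_mosaic(self, trio_cohort):
        co = trio_cohort
        meta = co.meta.set_index("iid")
        iid = co.targets()[0]
        fa = meta.loc[iid, "father"]
        for chrom in co.chromosomes:
            child = co.haplotypes(iid, chrom, which="truth")
            fh = co.haplotypes(fa, chrom, which="truth")
            assert ((child[0] == fh[0]) | (child[0] == fh[1])).all()

    def test_rejects_bad_config(self):
        with pytest.raises(ValueError):
            SimConfig(n_families=0).validate()
        with pytest.raises(ValueError):
            SimConfig(family_menu={"trio": 0.5}).validate()
        with pytest.raises(ValueError):
            SimConfig(family_menu={"castle": 1.0}).validate()


class TestCorrupt:
    def test_zero_rates_leave_phase_intact_up_to_orientation(self, rng):
        cfg = SimConfig(n_families=5, family_menu={"trio": 1.0},
                        chromosomes=["22"], n_variants=300,
                        genotype_error_rate=0.0, switch_error_rate=0.0,
                        seed=2)
        co = simulate_cohort(cfg)
        for i in range(len(co.meta)):
            t = co.truth["22"][i]
            o = co.obs["22"][i]
            same = (o == t).all()
            swapped = (o == t[::-1]).all()
            assert same or swapped

    def test_switch_count_scales_with_rate_and_length(self, rng):
        cfg = SimConfig(n_families=40, family_menu={"trio": 1.0},
                        chromosomes=["22"], n_variants=400,
                        genotype_error_rate=0.0, switch_error_rate=0.0,
                        seed=4)
        co = simulate_cohort(cfg)
        s = 0.05
        corrupt(co, 0.0, s, np.random.default_rng(0))
        length = co.gmap.length_cm("22", "avg")
        n_switch = []
        for i in range(len(co.meta)):
            t = co.truth["22"][i]
            o = co.obs["22"][i]
            het = t[0] != t[1]
            ori = (o[0][het] != t[0][het]).astype(int)
            n_switch.append(int((np.diff(ori) != 0).sum()))
        expected = s * length
        assert np.mean(n_switch) == pytest.approx(expected, rel=0.25)

    def test_genotype_error_count_is_binomial(self, rng):
        cfg = SimConfig(n_families=40, family_menu={"trio": 1.0},
                        chromosomes=["22"], n_variants=500,
                        genotype_error_rate=0.0, switch_error_rate=0.0,
                        seed=6)
        co = simulate_cohort(cfg)
        corrupt(co, 0.01, 0.0, np.random.default_rng(0))
        g_t = co.genotypes("22", which="truth")
        g_o = co.genotypes("22")
        n_calls = g_t.size
        n_flips = int((g_t != g_o).sum())
        assert n_flips == pytest.approx(0.01 * n_calls, rel=0.2)

    def test_rejects_invalid_rates(self, trio_cohort):
        with pytest.raises(ValueError):
            corrupt(trio_cohort, -0.1, 0.0, np.random.default_rng(0))


class TestPhenotypes:
    def test_null_effects_leave_trait_independent_of_genotype(self):
        from scipy import stats

        cfg = SimConfig(n_families=120, family_menu={"trio": 1.0},
                        chromosomes=["22"], n_variants=100, seed=8)
        co = simulate_cohort(cfg)
        ph = simulate_phenotypes(
            co, [{"chrom": "22", "index": 5, "beta_pat": 0, "beta_mat": 0}],
            np.random.default_rng(0),
        )
        g = co.genotypes("22", which="truth")[:, 5]
        r, p = stats.pearsonr(g, ph["phenotype"])
        assert p > 0.01

    def test_bipolar_effects_cancel_additively_but_not_by_parent(self):
        cfg = SimConfig(n_families=400, family_menu={"trio": 1.0},
                        chromosomes=["22"], n_variants=100, seed=8)
        co = simulate_cohort(cfg)
        b = 0.8
        ph = simulate_phenotypes(
            co, [{"chrom": "22", "index": 7, "beta_pat": b, "beta_mat": -b}],
            np.random.default_rng(0), noise_sd=0.5,
        )
        y = ph["phenotype"].to_numpy()
        g = co.genotypes("22", which="truth")[:, 7]
        pat = co.truth["22"][:, 0, 7]
        add_effect = np.polyfit(g, y, 1)[0]
        het = g == 1
        contrast = y[het & (pat == 1)].mean() - y[het & (pat == 0)].mean()
        assert abs(add_effect) < 0.15
        assert contrast == pytest.approx(2 * b, abs=0.35)

    def test_scan_recovers_parental_betas(self):
        from pofokit.pipeline import truth_encoding
        from pofokit.poescan import assoc_scan

        cfg = SimConfig(n_families=1700, family_menu={"trio": 1.0},
                        chromosomes=["22"], n_variants=60, seed=12)
        co = simulate_cohort(cfg)
        effects = [{"chrom": "22", "index": 3, "beta_pat": 0.3,
                    "beta_mat": 0.1}]
        ph = simulate_phenotypes(co, effects, np.random.default_rng(1))
        encoding = truth_encoding(co, "22")
        # one child per family: rows are then independent across families
        rows = np.array([co.index(t) for t in co.targets()])
        enc = {"ds_mat": encoding.ds_mat[rows], "ds_pat": encoding.ds_pat[rows]}
        y = ph["phenotype"].to_numpy()[rows]
        for mode, beta in (("pat", 0.3), ("mat", 0.1)):
            res = assoc_scan(enc, y, None, mode)
            row = res.iloc[3]
            assert abs(row["beta"] - beta) < 2.5 * row["se"]

    def test_unknown_variant_rejected(self, trio_cohort):
        with pytest.raises(KeyError):
            simulate_phenotypes(
                trio_cohort,
                [{"chrom": "99", "index": 0, "beta_pat": 1, "beta_mat": 0}],
                np.random.default_rng(0),
            )
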