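import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pofokit.poescan import (
    assoc_scan,
    classify_poe,
    conditional_scan,
    differential_z,
    h2_diff_z,
    inverse_normal_transform,
    load_known_poe_table,
    n_eff,
    or_ratio,
    prep_phenotype,
    prune,
    sex_diff_z,
    thresholds,
)


class TestPhenotypePrep:
    def test_int_is_symmetric_and_median_zero(self):
        rec = pd.DataFrame({"iid": list("abcde"), "value": [1, 2, 3, 4, 5]})
        out = prep_phenotype(rec)
        assert out.loc["c"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["a"] == pytest.approx(-out.loc["e"])

    def test_time_points_averaged_before_transform(self):
        rec = pd.DataFrame({"iid": ["a", "a", "b"], "value": [10, 14, 20]})
        means = rec.groupby("iid")["value"].mean()
        assert means["a"] == 12.0
        out = prep_phenotype(rec)
        assert out.loc["a"] < out.loc["b"]

    def test_matches_rank_quantile_oracle(self, rng):
        values = rng.normal(size=40) ** 3
        rec = pd.DataFrame({"iid": [f"i{k}" for k in range(40)],
                            "value": values})
        out = prep_phenotype(rec).to_numpy()
        ranks = stats.rankdata(values)
        expected = stats.norm.ppf((ranks - 0.5) / 40)
        np.testing.assert_allclose(np.sort(out), np.sort(expected))

    def test_binary_inclusion_exclusion_codes(self):
        rec = pd.DataFrame(
            {"iid": ["a", "b", "b", "c", "d"],
             "code": ["E11", "E11", "E10", "E66", "E10"]}
        )
        out = prep_phenotype(rec, kind="binary", include_codes={"E11"},
                             exclude_codes={"E10"})
        assert out.loc["a"] == 1.0
        assert out.loc["c"] == 0.0
        assert "b" not in out.index and "d" not in out.index

    def test_all_missing_rejected(self):
        rec = pd.DataFrame({"iid": [], "value": []})
        with pytest.raises(ValueError):
            prep_phenotype(rec)


def _encoding(rng, n, m, p=0.4):
    ap_pat = (rng.random((n, m)) < p).astype(float)
    ap_mat = (rng.random((n, m)) < p).astype(float)
    return {"ds_mat": ap_mat, "ds_pat": ap_pat}


class TestAssocScan:
    def test_recovers_parental_effect_and_diff_detects(self, rng):
        n = 5000
        enc = _encoding(rng, n, 5)
        y = 0.3 * enc["ds_pat"][:, 2] + rng.normal(0, 1, n)
        pat = assoc_scan(enc, y, None, "pat")
        assert abs(pat.loc[2, "beta"] - 0.3) < 2 * pat.loc[2, "se"]
        diff = assoc_scan(enc, y, None, "diff")
        assert diff.loc[2, "p"] < 1e-3

    def test_bipolar_cancels_additively_but_not_differentially(self, rng):
        n = 4000
        enc = _encoding(rng, n, 3)
        b = 0.4
        y = b * enc["ds_pat"][:, 1] - b * enc["ds_mat"][:, 1] + rng.normal(
            0, 1, n
        )
        add = assoc_scan(enc, y, None, "add")
        diff = assoc_scan(enc, y, None, "diff")
        z_add = abs(add.loc[1, "beta"] / add.loc[1, "se"])
        z_diff = abs(diff.loc[1, "beta"] / diff.loc[1, "se"])
        assert z_add < 3
        assert z_diff > 6

    def test_covariates_absorb_confounding(self, rng):
        n = 3000
        enc = _encoding(rng, n, 2)
        sex = rng.integers(0, 2, n).astype(float)
        y = 2.0 * sex + rng.normal(0, 1, n)
        res = assoc_scan(enc, y, sex[:, None], "add")
        assert (res["p"] > 1e-3).all()

    def test_binary_trait_logistic(self, rng):
        n = 3000
        enc = _encoding(rng, n, 2)
        eta = 0.8 * (enc["ds_pat"][:, 0] + enc["ds_mat"][:, 0]) - 0.5
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        res = assoc_scan(enc, y, None, "add", kind="binary")
        assert abs(res.loc[0, "beta"] - 0.8) < 3 * res.loc[0, "se"]
        assert res.loc[0, "p"] < 1e-4

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            assoc_scan(_encoding(rng, 10, 1), np.zeros(10), None, "dominance")


class TestConditional:
    def test_conditioning_on_self_is_flagged(self, rng):
        n = 1000
        enc = _encoding(rng, n, 1)
        y = rng.normal(size=n)
        lead = enc["ds_pat"][:, 0] + enc["ds_mat"][:, 0]
        res = conditional_scan(enc, y, None, "add", lead)
        assert np.isnan(res.loc[0, "p"]) or res.loc[0, "se"] > 1e3

    def test_proxy_signal_vanishes_after_conditioning(self, rng):
        n = 4000
        ap_pat = (rng.random(n) < 0.5).astype(float)
        ap_mat = (rng.random(n) < 0.5).astype(float)
        # proxy: nearly perfect LD copy of the causal variant
        flip = rng.random(n) < 0.02
        enc = {
            "ds_mat": np.column_stack([ap_mat, np.where(flip, 1 - ap_mat,
                                                        ap_mat)]),
            "ds_pat": np.column_stack([ap_pat, np.where(flip, 1 - ap_pat,
                                                        ap_pat)]),
        }
        y = 0.5 * (ap_pat + ap_mat) + rng.normal(0, 1, n)
        naive = assoc_scan(enc, y, None, "add")
        assert naive.loc[1, "p"] < 1e-10
        lead = enc["ds_pat"][:, 0] + enc["ds_mat"][:, 0]
        cond = conditional_scan(enc, y, None, "add", lead)
        assert cond.loc[1, "p"] > 1e-3


class TestDifferentialZ:
    def test_equal_effects_give_zero(self):
        z, p = differential_z(0.2, 0.05, 0.2, 0.05)
        assert z == 0.0 and p == 1.0

    def test_published_total_protein_row(self):
        """Summary-statistic Z for the ATP10A total-protein signal."""
        z, p = differential_z(0.101, 0.032, -0.106, 0.032)
        assert z == pytest.approx(4.574, abs=0.001)
        assert p == pytest.approx(4.8e-6, rel=0.05)

    def test_doubling_errors_halves_z(self):
        z1, _ = differential_z(0.3, 0.05, 0.1, 0.05)
        z2, _ = differential_z(0.3, 0.10, 0.1, 0.10)
        assert z1 == pytest.approx(2 * z2)

    def test_antisymmetric_under_parent_swap(self):
        z1, _ = differential_z(0.3, 0.04, 0.1, 0.06)
        z2, _ = differential_z(0.1, 0.06, 0.3, 0.04)
        assert z1 == pytest.approx(-z2)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            differential_z(0.1, 0.0, 0.2, 0.05)


class TestClassify:
    @pytest.mark.parametrize(
        "z_pat,z_mat,expected",
        [
            (-5.0, 3.4, "bipolar"),
            (-6.75, 1.25, "paternal"),
            (-15.25, -8.5, "paternal_asymmetric"),
            (-1.53, -11.44, "maternal"),
            (-8.5, -15.25, "maternal_asymmetric"),
            (0.0, 3.0, "unclassified"),
            (np.nan, 3.0, "unclassified"),
        ],
    )
    def test_rules(self, z_pat, z_mat, expected):
        assert classify_poe(z_pat, z_mat) == expected

    def test_parent_swap_maps_classes(self, rng):
        swap = {"maternal": "paternal", "paternal": "maternal",
                "maternal_asymmetric": "paternal_asymmetric",
                "paternal_asymmetric": "maternal_asymmetric",
                "bipolar": "bipolar", "unclassified": "unclassified"}
        for _ in range(50):
            zp, zm = rng.normal(0, 5, 2)
            assert classify_poe(zm, zp) == swap[classify_poe(zp, zm)]

    def test_published_rows_reproduce_reported_classes(self):
        tab = load_known_poe_table()
        for _, r in tab.iterrows():
            got = classify_poe(r["beta_pat"] / r["se_pat"],
                               r["beta_mat"] / r["se_mat"])
            expected = {"B": "bipolar", "M": "maternal", "P": "paternal",
                        "PA": "paternal_asymmetric",
                        "MA": "maternal_asymmetric"}[r["poe_class"]]
            assert got == expected, r["rsid"]


class TestNeff:
    def test_identity_counts_every_trait(self):
        assert n_eff(np.eye(7)) == 7

    def test_perfectly_correlated_pair_counts_once(self):
        assert n_eff(np.ones((2, 2))) == 1

    def test_three_independent_blocks(self):
        m = np.kron(np.eye(3), np.ones((4, 4)))
        assert n_eff(m) == 3

    def test_non_psd_rejected(self):
        m = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            n_eff(m)


class TestThresholds:
    def test_genomewide_divided_by_effective_traits(self):
        t = thresholds(n_eff_traits=48)
        assert t["genomewide"] == pytest.approx(5e-8 / 48)

    def test_imprinted_suggestive_and_significant(self):
        t = thresholds(n_eff_traits=48, n_imprinted_tests=16_574)
        assert t["imprinted_suggestive"] == pytest.approx(3.01e-6, rel=0.01)
        assert t["imprinted_significant"] == pytest.approx(
            t["imprinted_suggestive"] / 48
        )

    def test_additive_region_bonferroni(self):
        assert thresholds(n_additive=14)["additive_region"] == pytest.approx(
            0.05 / 14
        )


class TestPrune:
    def test_nearby_weaker_hit_removed(self):
        res = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [1_000_000, 1_100_000],
             "p": [1e-10, 1e-6]}
        )
        kept = prune(res)
        assert len(kept) == 1 and kept["p"].iloc[0] == 1e-10

    def test_distant_and_uncorrelated_hits_retained(self, rng):
        res = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [1_000_000, 2_000_000],
             "p": [1e-10, 1e-6]}
        )
        g = rng.integers(0, 3, size=(500, 2)).astype(float)
        kept = prune(res, genotypes=g)
        assert len(kept) == 2

    def test_high_ld_removed_despite_distance(self, rng):
        g0 = rng.integers(0, 3, 500).astype(float)
        g = np.column_stack([g0, g0])
        res = pd.DataFrame(
            {"chrom": ["1", "1"], "pos": [1_000_000, 5_000_000],
             "p": [1e-10, 1e-6]}
        )
        kept = prune(res, genotypes=g)
        assert len(kept) == 1


class TestSummaryContrasts:
    def test_sex_difference_zero_when_equal(self):
        z, p = sex_diff_z(0.2, 0.05, 0.2, 0.05)
        assert z == 0.0 and p == 1.0

    def test_sex_swap_flips_sign(self):
        z1, _ = sex_diff_z(0.3, 0.05, 0.1, 0.05)
        z2, _ = sex_diff_z(0.1, 0.05, 0.3, 0.05)
        assert z1 == pytest.approx(-z2)

    def test_equal_or_gives_unit_ratio(self):
        r, ci = or_ratio(1.2, (1.1, 1.3), 1.2, (1.1, 1.3))
        assert r == pytest.approx(1.0)
        assert ci[0] < 1.0 < ci[1]

    def test_parent_swap_inverts_ratio(self):
        r1, _ = or_ratio(1.14, (1.08, 1.21), 0.91, (0.86, 0.96))
        r2, _ = or_ratio(0.91, (0.86, 0.96), 1.14, (1.08, 1.21))
        assert r1 == pytest.approx(1 / r2)

    def test_inverted_ci_rejected(self):
        with pytest.raises(ValueError):
            or_ratio(1.1, (1.2, 1.0), 1.0, (0.9, 1.1))

    def test_h2_difference_arithmetic(self):
        z, _ = h2_diff_z(0.2, 0.05, 0.1, 0.05)
        assert z == pytest.approx(np.sqrt(2), abs=1e-6)

    def test_h2_subset_weighting(self):
        z_full, _ = h2_diff_z(0.2, 0.05, 0.1, 0.05, weight_a=0.5)
        z_manual, _ = h2_diff_z(0.1, 0.05, 0.1, 0.05)
        assert z_full == pytest.approx(z_manual)
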