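"""O'Brien / dLC combination, sigma estimation, locus collapsing, genes."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from pgxpersona.containers import DataError
from pgxpersona.crosstrait import (
    CrossTraitMeta,
    annotate_genes,
    combine_traits,
    dlc_statistic,
    estimate_sigma,
    lead_loci,
    nearest_gene,
    ob_statistic,
    p_to_z,
)


def make_stats(ids, p, beta, chrom=1, bp=None, a1="G", a2="A"):
    m = len(ids)
    bp = np.arange(1, m + 1) * 1000 if bp is None else bp
    return pd.DataFrame(
        {
            "CHR": chrom, "BP": bp,
            "A1": [a1] * m if isinstance(a1, str) else a1,
            "A2": [a2] * m if isinstance(a2, str) else a2,
            "BETA": np.asarray(beta, float), "SE": 0.1,
            "P": np.asarray(p, float), "N": 865,
        },
        index=pd.Index(ids, name="SNP"),
    )


class TestPToZ:
    def test_no_evidence_gives_zero(self):
        assert p_to_z(1.0, +1) == 0.0
        assert p_to_z(1.0, -1) == 0.0

    def test_standard_quantiles(self):
        assert p_to_z(0.05, +1) == pytest.approx(1.95996, abs=1e-4)
        assert p_to_z(3.24e-3, +1) == pytest.approx(2.944, abs=1e-3)
        assert p_to_z(0.05, -1) == pytest.approx(-1.95996, abs=1e-4)

    def test_invalid_p_rejected(self):
        with pytest.raises(DataError):
            p_to_z(0.0, +1)
        with pytest.raises(DataError):
            p_to_z(1.5, +1)


class TestObStatistic:
    def test_single_statistic_reduces_to_its_own_p(self):
        z1 = 2.3
        t, p = ob_statistic([z1], sigma=np.array([[1.0]]))
        assert t == pytest.approx(z1)
        assert p == pytest.approx(2 * norm.sf(abs(z1)), rel=1e-12)

    def test_equal_statistics_closed_form(self):
        c = 1.7
        t, _ = ob_statistic([c, c])
        assert t == pytest.approx(c * np.sqrt(2.0), rel=1e-12)

    def test_identity_sigma_matches_classic_combination(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            z = rng.standard_normal(2) * 3
            t, _ = ob_statistic(z)
            assert t == pytest.approx((z[0] + z[1]) / np.sqrt(2.0), abs=1e-12)

    def test_singular_sigma_rejected(self):
        with pytest.raises(DataError):
            ob_statistic([1.0, 1.0], sigma=np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestDlcStatistic:
    def test_concordant_signals_equal_obrien(self):
        z = [2.0, 3.0]
        t_ob, p_ob = ob_statistic(z)
        t_dlc, p_dlc, w = dlc_statistic(z)
        assert t_dlc == pytest.approx(t_ob, rel=1e-12)
        assert p_dlc == pytest.approx(p_ob, rel=1e-12)
        np.testing.assert_allclose(w, [1, 1] / np.sqrt(2))

    def test_opposed_signals_select_sign_aligned_weight(self):
        z = [-2.576, 6.211]
        t, p, w = dlc_statistic(z)
        assert abs(t) == pytest.approx((2.576 + 6.211) / np.sqrt(2.0), abs=1e-6)
        np.testing.assert_allclose(w, np.array([1, -1]) / np.sqrt(2))

    def test_projection_weight_returns_first_trait(self):
        z = [1.234, -9.0]
        t, p, _ = dlc_statistic(z, weight_set=[np.array([1.0, 0.0])])
        assert t == pytest.approx(1.234)
        assert p == pytest.approx(2 * norm.sf(1.234), rel=1e-12)

    def test_dlc_never_less_significant_than_obrien_under_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            z = rng.standard_normal(2) * 4
            _, p_ob = ob_statistic(z)
            _, p_dlc, _ = dlc_statistic(z)
            assert p_dlc <= p_ob + 1e-15

    def test_empty_weight_set_rejected(self):
        with pytest.raises(DataError):
            dlc_statistic([1.0, 2.0], weight_set=[])


class TestCombineTraits:
    def test_dual_rule_requires_both_nominal(self):
        s1 = make_stats(["a"], [0.5], [1.0])
        s2 = make_stats(["a"], [1e-30], [1.0])
        hits = combine_traits(s1, s2)
        assert bool(hits["genome_wide"].iloc[0])
        assert not bool(hits["both_nominal"].iloc[0])
        assert not bool(hits["pass_dual"].iloc[0])

    def test_null_pair_has_unit_combined_p(self):
        s1 = make_stats(["a"], [1.0], [0.1])
        s2 = make_stats(["a"], [1.0], [0.1])
        hits = combine_traits(s1, s2)
        assert hits["p_combined"].iloc[0] == pytest.approx(1.0)
        assert not hits["pass_dual"].iloc[0]

    def test_combined_p_is_min_of_both(self, small_cohort):
        stats = small_cohort["sumstats"]
        rng = np.random.default_rng(2)
        s2 = stats.copy()
        s2["BETA"] = rng.standard_normal(len(s2)) * 0.01
        s2["P"] = rng.uniform(size=len(s2))
        hits = combine_traits(stats, s2)
        np.testing.assert_allclose(
            hits["p_combined"], np.minimum(hits["p_ob"], hits["p_dlc"])
        )

    def test_symmetric_under_trait_swap(self):
        rng = np.random.default_rng(3)
        m = 50
        ids = [f"v{i}" for i in range(m)]
        s1 = make_stats(ids, rng.uniform(size=m), rng.standard_normal(m))
        s2 = make_stats(ids, rng.uniform(size=m), rng.standard_normal(m))
        a = combine_traits(s1, s2)
        b = combine_traits(s2, s1)
        np.testing.assert_allclose(a["p_combined"], b["p_combined"], rtol=1e-10)

    def test_allele_flip_is_harmonized(self):
        # same variant reported on the opposite strand orientation
        s1 = make_stats(["a"], [1e-5], [0.5], a1="G", a2="A")
        s2_flipped = make_stats(["a"], [1e-5], [-0.5], a1="A", a2="G")
        s2_same = make_stats(["a"], [1e-5], [0.5], a1="G", a2="A")
        h_flip = combine_traits(s1, s2_flipped)
        h_same = combine_traits(s1, s2_same)
        assert h_flip["z2"].iloc[0] == pytest.approx(h_same["z2"].iloc[0])
        assert h_flip["direction"].iloc[0] == "++"

    def test_empty_intersection_rejected(self):
        s1 = make_stats(["a"], [0.5], [1.0])
        s2 = make_stats(["b"], [0.5], [1.0])
        with pytest.raises(DataError):
            combine_traits(s1, s2)


class TestEstimateSigma:
    def test_identical_z_gives_unit_correlation(self):
        z = np.random.default_rng(4).standard_normal(5000)
        sigma = estimate_sigma(z, z)
        assert sigma[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_independent_traits_shrink_to_zero(self):
        rng = np.random.default_rng(5)
        z1 = rng.standard_normal(10_000)
        z2 = rng.standard_normal(10_000)
        sigma = estimate_sigma(z1, z2)
        assert abs(sigma[0, 1]) <= 0.03

    def test_known_overlap_correlation_recovered(self):
        rng = np.random.default_rng(6)
        r = 0.3
        m = 20_000
        shared = rng.standard_normal(m)
        z1 = np.sqrt(r) * shared + np.sqrt(1 - r) * rng.standard_normal(m)
        z2 = np.sqrt(r) * shared + np.sqrt(1 - r) * rng.standard_normal(m)
        sigma = estimate_sigma(z1, z2)
        assert sigma[0, 1] == pytest.approx(r, abs=0.05)

    def test_too_few_null_variants_rejected(self):
        z = np.full(200, 5.0)
        with pytest.raises(DataError):
            estimate_sigma(z, z)


class TestLeadLoci:
    def _hits(self, ids, chrom, bp, pcomb):
        return pd.DataFrame(
            {"CHR": chrom, "BP": bp, "p_combined": pcomb},
            index=pd.Index(ids, name="SNP"),
        )

    def test_linked_hits_share_a_locus(self, dosage_factory):
        rng = np.random.default_rng(7)
        x = rng.binomial(2, 0.5, 600).astype(float)
        y = x.copy()
        idx = rng.random(600) < 0.25
        y[idx] = rng.binomial(2, 0.5, idx.sum())  # r2 ~ 0.5
        genos = dosage_factory(np.column_stack([x, y]), bp=[1000, 2000])
        hits = self._hits(["v0", "v1"], 1, [1000, 2000], [1e-10, 1e-9])
        out = lead_loci(hits, genos)
        assert out["locus"].nunique() == 1
        assert out.loc["v0", "lead"] and not out.loc["v1", "lead"]

    def test_unlinked_hits_split_loci(self, dosage_factory):
        rng = np.random.default_rng(8)
        d = rng.binomial(2, 0.5, (2000, 2)).astype(float)
        genos = dosage_factory(d, bp=[1000, 2000])
        hits = self._hits(["v0", "v1"], 1, [1000, 2000], [1e-10, 1e-9])
        out = lead_loci(hits, genos)
        assert out["locus"].nunique() == 2
        assert out["lead"].all()

    def test_matches_greedy_oracle(self, small_cohort):
        genos = small_cohort["genotypes"]
        rng_master = np.random.default_rng(9)
        for _ in range(50):
            take = rng_master.choice(genos.n_variants, size=20, replace=False)
            ids = genos.variants.index[take]
            hits = pd.DataFrame(
                {
                    "CHR": genos.variants["CHR"].iloc[take].to_numpy(),
                    "BP": genos.variants["BP"].iloc[take].to_numpy(),
                    "p_combined": rng_master.uniform(size=20),
                },
                index=ids,
            )
            got = lead_loci(hits, genos, r2_link=0.1, window_bp=500_000)

            # independent greedy oracle
            order = hits.assign(_id=hits.index).sort_values(
                ["p_combined", "BP", "_id"]
            ).index
            locus = {}
            lead = {}
            next_locus = 0
            for sid in order:
                if sid in locus:
                    continue
                locus[sid] = next_locus
                lead[sid] = True
                for other in order:
                    if other in locus or hits.loc[other, "CHR"] != hits.loc[sid, "CHR"]:
                        continue
                    if abs(hits.loc[other, "BP"] - hits.loc[sid, "BP"]) > 500_000:
                        continue
                    r = np.corrcoef(
                        genos.dosage_vector(sid), genos.dosage_vector(other)
                    )[0, 1]
                    if r * r > 0.1:
                        locus[other] = next_locus
                        lead[other] = False
                next_locus += 1
            assert got["locus"].to_dict() == locus
            assert got["lead"].to_dict() == lead

    def test_missing_panel_variant_warns(self, dosage_factory):
        genos = dosage_factory(np.random.default_rng(10).binomial(2, 0.4, (100, 1)).astype(float))
        hits = self._hits(["v0", "ghost"], 1, [1000, 2000], [1e-9, 1e-8])
        with pytest.warns(UserWarning, match="excluded"):
            out = lead_loci(hits, genos)
        assert list(out.index) == ["v0"]


class TestNearestGene:
    GENES = pd.DataFrame(
        {
            "chrom": ["1", "1", "2"],
            "start": [100, 500, 100],
            "end": [200, 600, 300],
            "name": ["BETAGENE", "ALPHAGENE", "OTHER"],
        }
    )

    def test_inside_gene_body_distance_zero(self):
        name, dist = nearest_gene("1", 150, self.GENES)
        assert (name, dist) == ("BETAGENE", 0.0)

    def test_equidistant_tie_breaks_alphabetically(self):
        # position 350 (1-based 351): 150 bp right of BETAGENE end-1,
        # 150 bp left of ALPHAGENE start
        name, dist = nearest_gene("1", 351, self.GENES)
        assert name == "ALPHAGENE"
        assert abs(dist) == 150

    def test_far_position_is_intergenic(self):
        name, dist = nearest_gene("1", 10_000_000, self.GENES, max_distance=1000)
        assert name == "intergenic"
        assert np.isnan(dist)

    def test_malformed_interval_rejected(self):
        bad = pd.DataFrame(
            {"chrom": ["1"], "start": [200], "end": [100], "name": ["X"]}
        )
        with pytest.raises(DataError):
            nearest_gene("1", 150, bad)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        starts = np.sort(rng.choice(10_000, 30, replace=False))
        genes = pd.DataFrame(
            {
                "chrom": "1",
                "start": starts,
                "end": starts + rng.integers(50, 300, 30),
                "name": [f"G{i:02d}" for i in range(30)],
            }
        )
        for pos in rng.integers(1, 12_000, 100):
            name, dist = nearest_gene("1", int(pos), genes)
            pos0 = int(pos) - 1
            dists = np.where(
                pos0 < genes["start"], pos0 - genes["start"],
                np.where(pos0 >= genes["end"], pos0 - genes["end"] + 1, 0),
            )
            best = np.abs(dists).min()
            cand = sorted(genes["name"][np.abs(dists) == best])
            assert name == cand[0]
            assert abs(dist) == best


class TestModelObject:
    def test_model_fit_and_summary(self, small_cohort, tmp_path):
        import matplotlib

        matplotlib.use("Agg", force=True)
        stats = small_cohort["sumstats"]
        rng = np.random.default_rng(12)
        s2 = stats.copy()
        s2["BETA"] = rng.standard_normal(len(s2)) * 0.01
        s2["P"] = rng.uniform(size=len(s2))
        res = CrossTraitMeta(stats, s2, labels=("response", "neuroticism")).fit()
        assert {"p_ob", "p_dlc", "p_combined", "pass_dual"} <= set(res.hits.columns)
        res.assign_loci(small_cohort["genotypes"])
        genes = pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [50_000], "name": ["TOY1"]}
        )
        res.annotate(genes)
        assert "Cross-trait" in res.summary()
        res.plot_manhattan().figure.savefig(tmp_path / "mh.png")
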