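"""Association stage: orthogonalization, scans, combination, hits, loci."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mregle import assoc, synthgen
from mregle.assoc import (
    CombinedResult, clump, build_loci, combine_chi2, expected_chi2, manova_oracle,
    orthogonalize, overlap_known, variant_qc,
)
from mregle.models import EmbeddingMatrix


def _emb(values):
    return EmbeddingMatrix([f"s{i}" for i in range(values.shape[0])], values)


class TestOrthogonalize:
    def test_decorrelates_correlated_gaussians(self, rng):
        cov = 0.5 * np.ones((12, 12)) + 0.5 * np.eye(12)
        X = rng.multivariate_normal(np.zeros(12), cov, size=5000)
        pc = orthogonalize(_emb(X))
        c = np.corrcoef(pc.values, rowvar=False)
        np.fill_diagonal(c, 0.0)
        assert np.abs(c).max() < 1e-10
        assert pc.m == 12

    def test_constant_column_dropped_with_df_reduction(self, rng):
        X = rng.standard_normal((100, 5))
        X[:, 3] = 2.5
        with pytest.warns(UserWarning, match="zero-variance"):
            pc = orthogonalize(_emb(X))
        assert pc.m == 4 and len(pc.dropped_components) == 1

    def test_spans_same_subspace(self, rng):
        X = rng.standard_normal((200, 6))
        pc = orthogonalize(_emb(X))
        Xc = X - X.mean(axis=0)
        back = pc.values @ pc.rotation.T
        assert np.allclose(back, Xc, atol=1e-10)

    def test_needs_more_samples_than_dims(self, rng):
        with pytest.raises(ValueError):
            orthogonalize(_emb(rng.standard_normal((5, 8))))


class TestVariantQc:
    def _table(self, **overrides):
        base = dict(maf=0.2, info=0.99, missing_frac=0.0, hwe_p=0.5)
        base.update(overrides)
        return pd.DataFrame([{"id": "v", **base}])

    def test_maf_boundary_inclusive(self):
        assert len(variant_qc(self._table(maf=0.001))) == 1
        assert len(variant_qc(self._table(maf=0.000999))) == 0

    def test_hwe_boundary_strict(self):
        assert len(variant_qc(self._table(hwe_p=1.0e-10))) == 0
        assert len(variant_qc(self._table(hwe_p=1.001e-10))) == 1

    def test_each_filter_removes_exactly_one(self):
        tab = pd.DataFrame([
            {"id": "clean", "maf": 0.2, "info": 0.99, "missing_frac": 0.0, "hwe_p": 0.5},
            {"id": "low_maf", "maf": 0.0005, "info": 0.99, "missing_frac": 0.0, "hwe_p": 0.5},
            {"id": "low_info", "maf": 0.2, "info": 0.5, "missing_frac": 0.0, "hwe_p": 0.5},
            {"id": "missing", "maf": 0.2, "info": 0.99, "missing_frac": 0.2, "hwe_p": 0.5},
            {"id": "hwe", "maf": 0.2, "info": 0.99, "missing_frac": 0.0, "hwe_p": 1e-12},
        ])
        kept = variant_qc(tab)
        assert list(kept["id"]) == ["clean"]

    def test_missing_column_skips_filter_with_warning(self):
        tab = self._table().drop(columns=["info"])
        with pytest.warns(UserWarning, match="info"):
            assert len(variant_qc(tab)) == 1

    def test_info_and_missing_boundaries(self):
        assert len(variant_qc(self._table(info=0.8))) == 1
        assert len(variant_qc(self._table(missing_frac=0.05))) == 1


class TestAssocScan:
    def test_null_calibration(self, rng):
        gm = synthgen.simulate_genotypes(400, 2000, seed=0)
        y = rng.standard_normal(400)
        tab = assoc.assoc_scan_all(y[:, None], gm)
        p = tab.p[~np.isnan(tab.p[:, 0]), 0]
        rate = np.mean(p < 0.05)
        se = np.sqrt(0.05 * 0.95 / p.size)
        assert abs(rate - 0.05) < 2.5 * se

    def test_perfect_association_floors_p(self, rng):
        g = rng.binomial(2, 0.4, 500).astype(float)
        res = assoc.assoc_scan(g.copy(), g)
        assert res["chi2"] > 1e6 or np.isinf(res["chi2"])
        assert res["p"] >= np.finfo(float).tiny

    def test_covariate_adjustment_removes_confounding(self, rng):
        g = rng.binomial(2, 0.4, 2000).astype(float)
        conf = g + rng.standard_normal(2000)
        y = conf + rng.standard_normal(2000)  # y associates with g only via conf
        raw = assoc.assoc_scan(y, g)
        adj = assoc.assoc_scan(y, g, covariates=conf[:, None])
        assert raw["chi2"] > 50
        assert adj["chi2"] < 9

    def test_collinear_covariates_rejected(self, rng):
        g = rng.binomial(2, 0.4, 100).astype(float)
        y = rng.standard_normal(100)
        with pytest.raises(ValueError, match="collinear"):
            assoc.assoc_scan(y, g, covariates=np.column_stack([g, g]))

    def test_constant_dosage_rejected_single_and_na_batch(self, rng):
        y = rng.standard_normal(50)
        with pytest.raises(ValueError, match="monomorphic"):
            assoc.assoc_scan(y, np.ones(50))
        gm = synthgen.simulate_genotypes(50, 3, maf=0.4, seed=1)
        gm.dosages[:, 1] = 1.0
        tab = assoc.assoc_scan_all(y[:, None], gm)
        assert np.isnan(tab.chi2[1, 0]) and not np.isnan(tab.chi2[0, 0])

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        g = rng.binomial(2, 0.3, 300).astype(float)
        cov = rng.standard_normal((300, 3))
        y = 0.2 * g + cov @ [0.5, -0.3, 0.1] + rng.standard_normal(300)
        ours = assoc.assoc_scan(y, g, covariates=cov)
        X = sm.add_constant(np.column_stack([g, cov]))
        fit = sm.OLS(y, X).fit()
        assert ours["beta"] == pytest.approx(fit.params[1], rel=1e-10)
        assert ours["se"] == pytest.approx(fit.bse[1], rel=1e-10)


class TestCombineChi2:
    def _assoc(self, chi2):
        chi2 = np.atleast_2d(np.asarray(chi2, dtype=float))
        p = chi2.shape[0]
        variants = pd.DataFrame({"id": [f"v{i}" for i in range(p)],
                                 "chrom": "1", "pos": np.arange(1, p + 1)})
        return assoc.AssocTable(variants, np.sqrt(chi2), np.ones_like(chi2), chi2,
                                stats.chi2.sf(chi2, 1), n=100, covariate_names=[])

    def test_single_coordinate_identity(self):
        res = combine_chi2(self._assoc([[3.2]]))
        assert res.table["p"].iloc[0] == pytest.approx(stats.chi2.sf(3.2, 1), rel=1e-12)

    def test_all_zero_chi2_gives_p_one(self):
        res = combine_chi2(self._assoc([[0.0, 0.0, 0.0]]))
        assert res.table["p"].iloc[0] == 1.0

    def test_df2_closed_form(self):
        res = combine_chi2(self._assoc([[3.84, 3.84]]))
        assert res.table["p"].iloc[0] == pytest.approx(np.exp(-7.68 / 2.0), rel=1e-12)

    def test_zero_chi2_coordinate_increases_p(self):
        base = combine_chi2(self._assoc([[5.0, 4.0]]))
        padded = combine_chi2(self._assoc([[5.0, 4.0, 0.0]]))
        assert padded.table["sum_chi2"].iloc[0] == base.table["sum_chi2"].iloc[0]
        assert padded.df == base.df + 1
        assert padded.table["p"].iloc[0] > base.table["p"].iloc[0]


class TestManovaOracle:
    def test_m1_reduces_to_univariate_wald(self, rng):
        g = rng.binomial(2, 0.3, 500).astype(float)
        y = 0.1 * g + rng.standard_normal(500)
        uni = assoc.assoc_scan(y, g)
        assert manova_oracle(y[:, None], g) == pytest.approx(uni["p"], abs=1e-10)

    def test_matches_statsmodels_manova(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        g = rng.binomial(2, 0.3, 400).astype(float)
        Y = rng.standard_normal((400, 3))
        Y[:, 0] += 0.15 * g
        ours = manova_oracle(Y, g)
        df = pd.DataFrame(Y, columns=["y1", "y2", "y3"]).assign(g=g)
        fit = MANOVA.from_formula("y1 + y2 + y3 ~ g", data=df)
        res = fit.mv_test().results["g"]["stat"]
        wilks = float(res.loc["Wilks' lambda", "Value"])
        v_e = 400 - 2  # n minus rank of (intercept, g) design
        stat = v_e * (1 - wilks) / wilks
        assert ours == pytest.approx(float(stats.chi2.sf(stat, df=3)), rel=1e-6)

    def test_null_asymptotic_equivalence_with_combined(self, rng):
        diffs = []
        for i in range(200):
            g = rng.binomial(2, 0.3, 1500).astype(float)
            Y = rng.standard_normal((1500, 5))
            pc = orthogonalize(_emb(Y))
            gm = synthgen.GenotypeMatrix(
                [f"s{k}" for k in range(1500)], g[:, None],
                pd.DataFrame({"id": ["v0"], "chrom": "1", "pos": [1], "ref": "A",
                              "alt": "G", "maf": 0.3, "info": 1.0,
                              "missing_frac": 0.0, "hwe_p": 1.0}))
            comb = assoc.combine_pc(pc, gm)
            diffs.append(abs(comb.table["p"].iloc[0] - manova_oracle(Y, g)))
        assert np.median(diffs) < 0.01


def _panel(dosages, positions, chrom=None):
    dosages = np.asarray(dosages, dtype=float)
    p = dosages.shape[1]
    chrom = chrom or ["1"] * p
    var = pd.DataFrame({"id": [f"v{i}" for i in range(p)], "chrom": chrom,
                        "pos": positions, "ref": "A", "alt": "G", "maf": 0.3,
                        "info": 1.0, "missing_frac": 0.0, "hwe_p": 1.0})
    return synthgen.GenotypeMatrix([f"s{i}" for i in range(dosages.shape[0])],
                                   dosages, var)


def _combined(pvals, positions, chrom=None):
    p = len(pvals)
    tab = pd.DataFrame({"id": [f"v{i}" for i in range(p)],
                        "chrom": chrom or ["1"] * p, "pos": positions,
                        "sum_chi2": stats.chi2.isf(pvals, 10), "df": 10,
                        "p": pvals, "log10p": np.log10(pvals)})
    return CombinedResult(tab, 10)


class TestClump:
    def test_single_significant_variant(self, rng):
        G = rng.binomial(2, 0.3, (200, 3)).astype(float)
        combined = _combined([1e-9, 0.5, 0.9], [100, 200, 300])
        hits = clump(combined, _panel(G, [100, 200, 300]))
        assert len(hits) == 1 and hits[0].variant_id == "v0"
        assert [m[0] for m in hits[0].members] == ["v0"]

    def test_correlated_pair_forms_one_clump(self, rng):
        # construct two dosage columns with squared correlation ~0.5
        n = 20_000
        g1 = rng.binomial(2, 0.5, n).astype(float)
        noise = rng.binomial(2, 0.5, n).astype(float)
        mix = rng.random(n) < 0.707
        g2 = np.where(mix, g1, noise)
        r2 = np.corrcoef(g1, g2)[0, 1] ** 2
        assert r2 > 0.3
        combined = _combined([1e-12, 1e-9], [1000, 2000])
        hits = clump(combined, _panel(np.column_stack([g1, g2]), [1000, 2000]))
        assert len(hits) == 1 and hits[0].variant_id == "v0"
        assert {m[0] for m in hits[0].members} == {"v0", "v1"}

    def test_different_chromosomes_stay_separate(self, rng):
        g = rng.binomial(2, 0.3, 200).astype(float)
        panel = _panel(np.column_stack([g, g]), [1000, 1000], chrom=["1", "2"])
        combined = _combined([1e-9, 1e-10], [1000, 1000], chrom=["1", "2"])
        hits = clump(combined, panel)
        assert len(hits) == 2

    def test_variant_absent_from_panel_warns(self, rng):
        G = rng.binomial(2, 0.3, (100, 1)).astype(float)
        tab = _combined([1e-9, 1e-9], [100, 200]).table
        combined = CombinedResult(tab, 10)
        with pytest.warns(UserWarning, match="absent"):
            hits = clump(combined, _panel(G, [100]))
        assert len(hits) == 1


class TestBuildLoci:
    def test_empty_hits_empty_loci(self, rng):
        G = rng.binomial(2, 0.3, (50, 2)).astype(float)
        assert build_loci([], _panel(G, [1, 2])) == []

    def test_gap_below_250kb_merges(self):
        hits = [assoc.Hit("a", "1", 1_100_000, 1e-9, 80.0, [("a", 1.0)]),
                assoc.Hit("b", "1", 1_350_000, 1e-9, 80.0, [("b", 1.0)])]
        # panel in perfect LD within each span, independent across spans
        rng = np.random.default_rng(0)
        g1 = rng.binomial(2, 0.5, 500).astype(float)
        g2 = rng.binomial(2, 0.5, 500).astype(float)
        panel = _panel(np.column_stack([g1, g1, g2, g2]),
                       [1_000_000, 1_200_000, 1_300_000, 1_400_000])
        panel.variants.loc[[0, 1], "id"] = ["a", "a2"]
        panel.variants.loc[[2, 3], "id"] = ["b", "b2"]
        hits[0].pos, hits[1].pos = 1_000_000, 1_300_000
        loci = build_loci(hits, panel)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (1_000_000, 1_400_000)

    def test_gap_exactly_250kb_not_merged(self):
        rng = np.random.default_rng(1)
        g1 = rng.binomial(2, 0.5, 500).astype(float)
        g2 = rng.binomial(2, 0.5, 500).astype(float)
        panel = _panel(np.column_stack([g1, g2]), [1_200_000, 1_450_000])
        hits = [assoc.Hit("v0", "1", 1_200_000, 1e-9, 80.0, [("v0", 1.0)]),
                assoc.Hit("v1", "1", 1_450_000, 1e-9, 80.0, [("v1", 1.0)])]
        assert len(build_loci(hits, panel)) == 2


class TestExpectedChi2:
    def test_mean_of_known_values(self):
        combined = _combined([1e-9, 1e-9, 1e-9], [1, 2, 3])
        combined.table["sum_chi2"] = [10.0, 20.0, 30.0]
        mean, se = expected_chi2(combined, ["v0", "v1", "v2"])
        assert mean == 20.0
        assert se == pytest.approx(10.0 / np.sqrt(3))

    def test_single_value_has_no_se(self):
        combined = _combined([1e-9], [1])
        combined.table["sum_chi2"] = [42.0]
        mean, se = expected_chi2(combined, ["v0"])
        assert mean == 42.0 and np.isnan(se)

    def test_empty_intersection_warns_nan(self):
        combined = _combined([1e-9], [1])
        with pytest.warns(UserWarning, match="no overlap"):
            mean, se = expected_chi2(combined, ["nope"])
        assert np.isnan(mean)


class TestOverlapKnown:
    def _loci(self, spans):
        return [assoc.Locus("1", s, e, ["h"]) for s, e in spans]

    def test_overlap_and_adjacency(self):
        known = pd.DataFrame({"chrom": ["1", "1"], "start": [150, 201], "end": [300, 300]})
        loci, counts = overlap_known(self._loci([(100, 200)]), known.iloc[:1])
        assert loci[0].known is True
        loci, counts = overlap_known(self._loci([(100, 200)]), known.iloc[1:])
        assert loci[0].known is False

    def test_counts(self):
        known = pd.DataFrame({"chrom": ["1", "1"], "start": [100, 5000],
                              "end": [200, 6000]})
        loci, counts = overlap_known(
            self._loci([(150, 180), (5500, 5600), (9000, 9100)]), known)
        assert counts == {"known": 2, "novel": 1}

    def test_bed_conversion_is_one_based_inclusive(self, tmp_path):
        bed = tmp_path / "known.bed"
        bed.write_text("1\t99\t200\n")
        known = assoc.read_bed_intervals(bed)
        assert known.iloc[0]["start"] == 100 and known.iloc[0]["end"] == 200

    def test_malformed_interval_reports_line(self):
        known = pd.DataFrame({"chrom": ["1"], "start": [500], "end": [100]})
        with pytest.raises(ValueError, match="line 1"):
            overlap_known(self._loci([(1, 2)]), known)


class TestGenomicInflation:
    def test_null_lambda_near_one(self, rng):
        gm = synthgen.simulate_genotypes(800, 2000, seed=5)
        Y = rng.standard_normal((800, 6))
        pc = orthogonalize(_emb(Y))
        lam = assoc.genomic_inflation(assoc.combine_pc(pc, gm))
        assert lam == pytest.approx(1.0, abs=0.05)
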