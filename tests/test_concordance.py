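import numpy as np
import pandas as pd
import pytest

from proteoconcord import concordance as cc
from proteoconcord import preprocess
from proteoconcord.io_config import OmicsMatrix, PairMap


def brute_spearman(x, y):
    """Independent midrank-Pearson oracle (pure python ranking)."""
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            for k in range(i, j + 1):
                ranks[order[k]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) *
           sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


class TestSpearman:
    def test_hand_cases(self):
        assert cc.spearman([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)
        assert cc.spearman([1, 1, 2], [1, 2, 3]) == pytest.approx(
            np.sqrt(3) / 2)

    def test_rank_invariance(self, rng):
        x = rng.normal(size=40)
        y = x ** 3 + 5  # strictly increasing transform
        assert cc.spearman(x, y) == pytest.approx(1.0)

    def test_constant_input_nan(self):
        assert np.isnan(cc.spearman([1, 1, 1], [1, 2, 3]))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            n = rng.integers(3, 200)
            x = rng.integers(0, 8, n).astype(float)   # heavy ties
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            assert cc.spearman(x, y) == pytest.approx(
                brute_spearman(x, y), abs=1e-12)


def _toy_matrices(rng, n_genes=40, n_samples=6):
    genes = [f"G{i}" for i in range(n_genes)]
    prots = [f"P_{g}" for g in genes]
    samples = [f"s{j}" for j in range(n_samples)]
    prot = OmicsMatrix(prots, samples,
                       rng.normal(size=(n_genes, n_samples)), "transformed")
    rna = OmicsMatrix(genes, samples,
                      rng.normal(size=(n_genes, n_samples)), "log_intensity")
    return prot, rna, PairMap(list(zip(prots, genes))), samples


class TestBuildPairSet:
    def test_intersection(self):
        prot = OmicsMatrix(["P_A", "P_B", "P_C"], ["s1", "s2"],
                           [[1, 1], [1, 1], [1, 1]], "counts")
        rna = OmicsMatrix(["A", "C"], ["s1", "s2"], [[0, 0], [0, 0]],
                          "log_intensity")
        pm = PairMap([("P_A", "A"), ("P_B", "B"), ("P_C", "C")])
        ps = cc.build_pair_set(prot, rna, pm, ["s1", "s2"])
        assert ps.pairs == [("P_A", "A"), ("P_C", "C")]

    def test_group_coverage_rule(self):
        # detected once in 38 samples; 10% of 38 needs ceil=4 -> excluded
        vals = np.zeros((1, 38), dtype=int)
        vals[0, 0] = 7
        prot = OmicsMatrix(["P_A"], [f"s{j}" for j in range(38)], vals,
                           "counts")
        rna = OmicsMatrix(["A"], prot.sample_ids,
                          np.zeros((1, 38)), "log_intensity")
        pm = PairMap([("P_A", "A")])
        with pytest.raises(ValueError, match="empty"):
            cc.build_pair_set(prot, rna, pm, prot.sample_ids)

    def test_group_dependent_pair_set_sizes(self):
        # strong abundance-dependent dropout + tumor shift -> tumor pair set
        # should be larger than the normal one
        from proteoconcord.synthetic_data import SimConfig, generate_cohort
        cfg = SimConfig(n_genes=500, n_tumors=20, n_normals=20,
                        detection_midpoint=6.0, detection_slope=1.0,
                        background_protein_fc=3.0,
                        calibrate_folds=False, calibrate=False, seed=5)
        cohort, _ = generate_cohort(cfg)
        filt, _ = preprocess.filter_features(cohort.protein)
        pt = cc.build_pair_set(filt, cohort.mrna, cohort.pairmap,
                               cohort.samples.samples_with_tissue("tumor"))
        pn = cc.build_pair_set(filt, cohort.mrna, cohort.pairmap,
                               cohort.samples.samples_with_tissue("normal"))
        assert len(pt) > len(pn)


class TestWithinSample:
    def test_monotone_sample_is_one(self, rng):
        prot, rna, pm, samples = _toy_matrices(rng)
        rna.values[:, 0] = np.exp(prot.values[:, 0])  # monotone transform
        ps = cc.build_pair_set(
            OmicsMatrix(prot.feature_ids, prot.sample_ids,
                        np.ones_like(prot.values, dtype=int), "counts"),
            rna, pm, samples)
        res = cc.within_sample_concordance(prot, rna, ps, samples)
        assert res.scores["s0"] == pytest.approx(1.0)

    def test_equals_brute_force_loop(self, rng):
        prot, rna, pm, samples = _toy_matrices(rng, n_genes=60)
        ps = cc.PairSet(list(pm.pairs), "all")
        res = cc.within_sample_concordance(prot, rna, ps, samples)
        for j, s in enumerate(samples):
            expected = brute_spearman(prot.values[:, j], rna.values[:, j])
            assert res.scores[s] == pytest.approx(expected, abs=1e-12)

    def test_too_few_pairs_is_na_with_reason(self, rng):
        prot, rna, pm, samples = _toy_matrices(rng, n_genes=10)
        ps = cc.PairSet(list(pm.pairs), "all")
        res = cc.within_sample_concordance(prot, rna, ps, samples)
        assert res.scores.isna().all()
        assert "insufficient" in res.na_reasons["s0"]

    def test_monotone_transform_invariance(self, rng):
        prot, rna, pm, samples = _toy_matrices(rng, n_genes=50)
        ps = cc.PairSet(list(pm.pairs), "all")
        base = cc.within_sample_concordance(prot, rna, ps, samples)
        warped = OmicsMatrix(prot.feature_ids, prot.sample_ids,
                             np.exp(prot.values), "transformed")
        res = cc.within_sample_concordance(warped, rna, ps, samples)
        pd.testing.assert_series_equal(base.scores, res.scores)


class TestPerPair:
    def test_equals_transposed_brute_force(self, rng):
        prot, rna, pm, _ = _toy_matrices(rng, n_genes=30, n_samples=12)
        ps = cc.PairSet(list(pm.pairs), "all")
        res = cc.per_pair_concordance(prot, rna, ps, prot.sample_ids)
        for i, (p, g) in enumerate(ps.pairs):
            expected = brute_spearman(prot.values[i], rna.values[i])
            assert res.scores[f"{p}|{g}"] == pytest.approx(expected, abs=1e-12)

    def test_needs_ten_samples(self, rng):
        prot, rna, pm, samples = _toy_matrices(rng, n_samples=6)
        ps = cc.PairSet(list(pm.pairs), "all")
        with pytest.raises(ValueError, match="10"):
            cc.per_pair_concordance(prot, rna, ps, samples)

    def test_stability_ordering(self, small_cohort):
        _, cohort, truth = small_cohort
        filt, _ = preprocess.filter_features(cohort.protein)
        sf = preprocess.size_factors(filt)
        rlog = preprocess.rlog_like(filt, sf, 5.0)
        tumors = cohort.samples.samples_with_tissue("tumor")
        ps = cc.build_pair_set(filt, cohort.mrna, cohort.pairmap, tumors)
        res = cc.per_pair_concordance(rlog, cohort.mrna, ps, tumors)
        rho = {k.split("|")[1]: v for k, v in res.scores.dropna().items()}
        ss = [v for g, v in rho.items()
              if truth.stability[g]["protein_stable"]
              and truth.stability[g]["mrna_stable"]]
        uu = [v for g, v in rho.items()
              if not truth.stability[g]["protein_stable"]
              and not truth.stability[g]["mrna_stable"]]
        assert np.mean(ss) > np.mean(uu)


class TestCompare:
    def test_exact_small_case(self):
        res = cc.ConcordanceResult(
            "within_sample",
            pd.Series({"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4}),
            pd.Series(50, index=list("abcd")))
        comp = cc.compare_concordance(res, {"a": "x", "b": "x",
                                            "c": "y", "d": "y"})
        assert comp.p == pytest.approx(1 / 3)

    def test_identical_groups(self):
        scores = pd.Series(np.r_[np.arange(10), np.arange(10)] / 10.0,
                           index=[f"s{i}" for i in range(20)])
        res = cc.ConcordanceResult("within_sample", scores,
                                   pd.Series(50, index=scores.index))
        labels = {f"s{i}": ("a" if i < 10 else "b") for i in range(20)}
        comp = cc.compare_concordance(res, labels)
        assert comp.p > 0.99

    def test_three_groups_uses_kruskal(self, rng):
        scores = pd.Series(rng.uniform(-1, 1, size=30),
                           index=[f"s{i}" for i in range(30)])
        res = cc.ConcordanceResult("within_sample", scores,
                                   pd.Series(50, index=scores.index))
        labels = {f"s{i}": f"g{i % 3}" for i in range(30)}
        assert cc.compare_concordance(res, labels).test == "kruskal_wallis"

    def test_null_p_uniform(self, rng):
        from scipy import stats
        ps = []
        for _ in range(500):
            x = rng.normal(size=35)
            _, p = cc.rank_sum_test(x[:20], x[20:])
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestStratified:
    def test_empty_exclusion_identical(self, rng):
        prot, rna, pm, samples = _toy_matrices(rng, n_genes=50)
        ps = cc.PairSet(list(pm.pairs), "all")
        base = cc.within_sample_concordance(prot, rna, ps, samples)
        out = cc.stratified_concordance(prot, rna, ps, samples, exclude=[])
        pd.testing.assert_series_equal(base.scores, out["retained"].scores)

    def test_abundance_sextile_gap(self):
        # high-contrast couplings: the per-stratum signal is attenuated by
        # selection on (mRNA-correlated) protein abundance, so the gap needs
        # a clear design effect to show in every bin
        from proteoconcord.synthetic_data import SimConfig, generate_cohort
        cfg = SimConfig(n_genes=1500, n_tumors=22, n_normals=16, seed=3,
                        coupling_tumor_mean=0.5, coupling_normal_mean=0.1,
                        coupling_by_subtype={}, coupling_sd=0.03,
                        de_fraction_up=0.0, de_fraction_down=0.0,
                        utr_fraction=0.0)
        cohort, _ = generate_cohort(cfg)
        filt, _ = preprocess.filter_features(cohort.protein)
        sf = preprocess.size_factors(filt)
        rlog = preprocess.rlog_like(filt, sf, 5.0)
        gaps = []
        for tissue in ("tumor", "normal"):
            samples = cohort.samples.samples_with_tissue(tissue)
            ps = cc.build_pair_set(filt, cohort.mrna, cohort.pairmap, samples)
            strat = cc.stratified_concordance(rlog, cohort.mrna, ps, samples,
                                              abundance_bins=6)
            gaps.append([res.scores.mean() for res in strat.values()])
        diffs = np.array(gaps[0]) - np.array(gaps[1])
        assert (diffs > 0).all()  # tumor > normal in every abundance sextile

    def test_ecm_exclusion_small_effect(self, small_cohort):
        _, cohort, truth = small_cohort
        filt, _ = preprocess.filter_features(cohort.protein)
        sf = preprocess.size_factors(filt)
        rlog = preprocess.rlog_like(filt, sf, 5.0)
        tumors = cohort.samples.samples_with_tissue("tumor")
        ps = cc.build_pair_set(filt, cohort.mrna, cohort.pairmap, tumors)
        base = cc.within_sample_concordance(rlog, cohort.mrna, ps, tumors)
        ecm_prots = [f"P_{g}" for g in truth.ecm_genes]
        out = cc.stratified_concordance(rlog, cohort.mrna, ps, tumors,
                                        exclude=ecm_prots)
        assert abs(base.scores.mean() - out["retained"].scores.mean()) < 0.02


class TestSubsetRobustness:
    def test_full_fraction_reproduces(self, rng):
        prot, rna, pm, samples = _toy_matrices(rng, n_genes=60)
        ps = cc.PairSet(list(pm.pairs), "all")
        full = cc.within_sample_concordance(prot, rna, ps, samples)
        df = cc.subset_robustness(prot, rna, ps, samples, 1.0, 5, seed=1)
        np.testing.assert_allclose(df["mean_rho"], full.scores.mean())

    def test_deterministic(self, rng):
        prot, rna, pm, samples = _toy_matrices(rng, n_genes=80)
        ps = cc.PairSet(list(pm.pairs), "all")
        a = cc.subset_robustness(prot, rna, ps, samples, 0.5, 10, seed=9)
        b = cc.subset_robustness(prot, rna, ps, samples, 0.5, 10, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_half_fraction_close_to_full(self, big_cohort):
        _, cohort, _ = big_cohort
        filt, _ = preprocess.filter_features(cohort.protein)
        sf = preprocess.size_factors(filt)
        rlog = preprocess.rlog_like(filt, sf, 5.0)
        tumors = cohort.samples.samples_with_tissue("tumor")
        ps = cc.build_pair_set(filt, cohort.mrna, cohort.pairmap, tumors)
        full = cc.within_sample_concordance(rlog, cohort.mrna, ps,
                                            tumors).scores.mean()
        df = cc.subset_robustness(rlog, cohort.mrna, ps, tumors, 0.5, 50,
                                  seed=11)
        dev = np.abs(df["mean_rho"] - full)
        # pair-sampling noise at ~2000 pairs; tightens with pair-set size
        assert dev.mean() < 0.02
        assert dev.max() < 0.05


class TestAdjustedAssociation:
    def test_orthogonal_covariate_keeps_correlation(self, rng):
        n = 40
        x = rng.normal(size=n)
        y = 0.8 * x + rng.normal(size=n) * 0.3
        z = np.r_[np.zeros(n // 2), np.ones(n // 2)]  # balanced, indep of x,y
        idx = [f"s{i}" for i in range(n)]
        res = cc.adjusted_association(pd.Series(y, idx), pd.Series(x, idx),
                                      pd.DataFrame({"z": z}, index=idx))
        raw = np.corrcoef(x, y)[0, 1]
        assert res["partial_correlation"] == pytest.approx(raw, abs=0.05)

    def test_hand_four_point_case(self):
        idx = list("abcd")
        res = cc.adjusted_association(
            pd.Series([1.0, 2, 3, 4], idx), pd.Series([1.0, 2, 3, 4], idx),
            pd.DataFrame({"c": [0.0, 0, 1, 1]}, index=idx))
        assert res["partial_correlation"] == pytest.approx(1.0)

    def test_collinear_names_column(self):
        idx = [f"s{i}" for i in range(10)]
        z = np.arange(10.0)
        cov = pd.DataFrame({"z1": z, "z2": 2 * z}, index=idx)
        with pytest.raises(ValueError, match="z2|z1"):
            cc.adjusted_association(pd.Series(z, idx), pd.Series(z, idx), cov)

    def test_confounded_predictor_loses_effect(self, rng):
        # coupling driven only by subtype; race correlated with subtype ->
        # subtype-adjusted race coefficient should be null
        hits = 0
        reps = 100
        for _ in range(reps):
            n = 60
            subtype = rng.choice(["A", "B", "C"], size=n)
            race = np.where(rng.uniform(size=n) <
                            np.where(subtype == "C", 0.7, 0.25), 1.0, 0.0)
            effect = {"A": 0.0, "B": 0.05, "C": 0.12}
            rho = np.array([effect[s] for s in subtype]) + \
                rng.normal(0, 0.04, n)
            idx = [f"s{i}" for i in range(n)]
            res = cc.adjusted_association(
                pd.Series(rho, idx), pd.Series(race, idx),
                pd.DataFrame({"subtype": subtype}, index=idx))
            if abs(res["t"]) < 2:
                hits += 1
        assert hits >= 0.9 * reps


class TestRecovery:
    def test_realized_vs_truth_correlation(self, big_cohort):
        _, _, truth = big_cohort
        t = pd.Series(truth.coupling)
        r = pd.Series(truth.realized_coupling)
        ok = r.notna()
        assert np.corrcoef(t[ok], r[ok])[0, 1] > 0.9
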