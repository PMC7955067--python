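import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from crisprmerge.benchmark import (
    biomarker_associations,
    empirical_fdr_recall,
    gene_pair_recovery,
    lineage_ami,
    nnmd,
    normlrt,
    oncogene_benchmark,
    subtype_rank_recall,
    unexpressed_fpr,
)
from crisprmerge.data import ReferenceSets, ScreenMetadata
from conftest import make_matrix, make_meta


class TestNNMD:
    def test_hand_computed_value(self):
        scores = pd.Series(
            {"e1": -1.0, "e2": -1.0, "n1": -0.5, "n2": 0.0, "n3": 0.5}
        )
        assert nnmd(scores, {"e1", "e2"}, {"n1", "n2", "n3"}) == pytest.approx(-2.0)

    def test_null_sets_give_near_zero(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=2000), index=[f"g{i}" for i in range(2000)])
        vals = [
            nnmd(scores, {f"g{i}" for i in range(0, 1000)},
                 {f"g{i}" for i in range(1000, 2000)})
        ]
        assert abs(np.mean(vals)) < 0.1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(-5, 5), st.floats(0.1, 10))
    def test_affine_equivariance(self, shift, scale):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        e = {f"g{i}" for i in range(10)}
        n = {f"g{i}" for i in range(10, 50)}
        base = nnmd(scores, e, n)
        assert nnmd(scores * scale + shift, e, n) == pytest.approx(base, rel=1e-9)

    def test_degenerate_null_rejected(self):
        scores = pd.Series({"e1": -1, "e2": -1, "n1": 0, "n2": 0})
        with pytest.raises(ValueError, match="degenerate"):
            nnmd(scores, {"e1", "e2"}, {"n1", "n2"})

    def test_quality_ordering_on_screens(self, small_cohort):
        # sabotaged (noisier) screen separates controls worse
        cfg, a, b, meta, refs, gt = small_cohort
        rng = np.random.default_rng(2)
        col = a.to_frame().iloc[:, 0]
        noisy = col + rng.normal(0, 5 * cfg.noise_sd, size=len(col))
        assert nnmd(col, refs.essentials, refs.non_essentials) < nnmd(
            noisy, refs.essentials, refs.non_essentials
        )


class TestUnexpressedFPR:
    def test_boundary_cases(self):
        scores = pd.Series(np.linspace(-2, 2, 100), index=[f"g{i}" for i in range(100)])
        top = {f"g{i}" for i in range(60, 80)}  # least depleted half
        assert unexpressed_fpr(scores, top) == 0.0
        bottom = {f"g{i}" for i in range(5)}  # at the minimum
        assert unexpressed_fpr(scores, bottom) == 1.0

    def test_random_screen_rate_near_fraction(self):
        rng = np.random.default_rng(3)
        rates = []
        for _ in range(300):
            s = pd.Series(rng.uniform(-1, 1, 400), index=[f"g{i}" for i in range(400)])
            unexp = [f"g{i}" for i in rng.choice(400, 50, replace=False)]
            rates.append(unexpressed_fpr(s, unexp))
        assert np.mean(rates) == pytest.approx(0.15, abs=0.02)


class TestEmpiricalFDRRecall:
    def _screen(self, seed=0, n_null=120):
        rng = np.random.default_rng(seed)
        null = pd.Series(rng.normal(0, 0.2, n_null),
                         index=[f"u{i}" for i in range(n_null)])
        ess = pd.Series(rng.normal(-2, 0.2, 40), index=[f"e{i}" for i in range(40)])
        rest = pd.Series(rng.normal(0, 0.2, 200), index=[f"r{i}" for i in range(200)])
        return pd.concat([null, ess, rest]), set(null.index), set(ess.index)

    def test_clear_essentials_fully_recalled(self):
        scores, unexp, ess = self._screen()
        assert empirical_fdr_recall(scores, unexp, ess, fdr=0.10) == 1.0

    def test_null_essentials_rarely_recalled(self):
        rng = np.random.default_rng(1)
        recalls = []
        for i in range(100):
            scores, unexp, _ = self._screen(seed=i)
            fake_e = {f"r{j}" for j in range(40)}  # drawn from the null
            recalls.append(empirical_fdr_recall(scores, unexp, fake_e, fdr=0.10))
        assert np.mean(recalls) < 0.1

    def test_fdr_zero_gives_zero_recall(self):
        scores, unexp, ess = self._screen()
        assert empirical_fdr_recall(scores, unexp, ess, fdr=0.0) == 0.0

    def test_small_null_rejected(self):
        scores, unexp, ess = self._screen(n_null=30)
        with pytest.raises(ValueError, match="null too small"):
            empirical_fdr_recall(scores, unexp, ess)

    def test_pvalues_superuniform_under_null(self):
        # empirical add-one p-values of null genes stochastically dominate
        # the uniform distribution
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(200):
            null = np.sort(rng.normal(size=100))
            genes = rng.normal(size=5)
            p = (1 + np.searchsorted(null, genes, side="right")) / (1 + null.size)
            pvals.extend(p)
        # P(p <= t) must not exceed t by more than sampling noise
        for t in (0.05, 0.1, 0.25, 0.5):
            assert np.mean(np.asarray(pvals) <= t) <= t + 0.03


class TestLineageAMI:
    def _clustered(self, sep=6.0, seed=0, n_per=10, k=3):
        rng = np.random.default_rng(seed)
        centers = rng.normal(0, sep, size=(k, 40))
        cols, labels = [], []
        for i in range(k):
            cols.append(centers[i][:, None] + rng.normal(0, 1, size=(40, n_per)))
            labels += [f"t{i}"] * n_per
        m = make_matrix(np.hstack(cols))
        meta = make_meta(m.screen_ids, lineages=labels)
        return m, meta

    def test_planted_clusters_give_high_ami(self):
        m, meta = self._clustered()
        res = lineage_ami(m, meta, n_genes=40, n_runs=20, seed=0)
        assert res.mean > 0.9
        assert res.p_value < 1e-6

    def test_random_labels_give_near_zero_ami(self):
        m, meta = self._clustered(sep=0.0, seed=1)
        res = lineage_ami(m, meta, n_genes=40, n_runs=20, seed=0)
        assert abs(res.mean) < 0.05

    def test_lineage_structure_recovered_in_cohort(self, integrated_default, default_cohort):
        _cfg, _a, _b, meta, _refs, _gt = default_cohort
        line_meta = meta.table.drop_duplicates("cell_line_id").copy()
        line_meta["screen_id"] = line_meta["cell_line_id"]
        res = lineage_ami(
            integrated_default.matrix, ScreenMetadata(line_meta),
            n_runs=30, seed=0,
        )
        assert res.mean > 0.2 and res.p_value < 1e-10


class TestSubtypeRecall:
    def test_separated_blocks_give_perfect_recall(self):
        rng = np.random.default_rng(0)
        blocks = []
        for i in range(2):
            center = rng.normal(0, 5, size=30)
            blocks.append(center[:, None] + rng.normal(0, 0.5, size=(30, 5)))
        m = make_matrix(np.hstack(blocks))
        meta = make_meta(m.screen_ids, subtypes=["s0"] * 5 + ["s1"] * 5)
        curve = subtype_rank_recall(m, meta)
        assert curve.at(1) == 1.0

    def test_shuffled_labels_match_permutation_null(self):
        rng = np.random.default_rng(1)
        k1 = []
        for _ in range(100):
            m = make_matrix(rng.normal(size=(30, 12)))
            labels = list(rng.permutation(["s0"] * 6 + ["s1"] * 6))
            meta = make_meta(m.screen_ids, subtypes=labels)
            k1.append(subtype_rank_recall(m, meta).at(1))
        # null: nearest of 11 candidates is same-subtype with prob 5/11
        assert np.mean(k1) == pytest.approx(5 / 11, abs=0.05)

    def test_single_subtype_rejected(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(10, 6)))
        meta = make_meta(m.screen_ids, subtypes=["s0"] * 6)
        with pytest.raises(ValueError, match="subtypes"):
            subtype_rank_recall(m, meta)


class TestNormLRT:
    def test_normal_data_gives_small_values(self):
        rng = np.random.default_rng(0)
        vals = [normlrt(rng.normal(size=200)).value for _ in range(30)]
        assert np.percentile(vals, 95) < 10

    def test_bimodal_profile_gives_large_value(self):
        rng = np.random.default_rng(1)
        null_vals = [normlrt(rng.normal(0, 0.3, 200)).value for _ in range(30)]
        x = np.concatenate([rng.normal(0, 0.3, 190), rng.normal(-3, 0.3, 10)])
        assert normlrt(x).value > np.percentile(null_vals, 99)

    def test_skewt_nests_normal(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            x = np.random.default_rng(seed).normal(size=60)
            r = normlrt(x)
            assert r.ll_skewt >= r.ll_normal - 0.01
            assert r.value >= -0.02

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="non-missing"):
            normlrt(np.zeros(10))


class TestBiomarkerAssociations:
    def _cohort(self, delta=0.0, seed=0, n_lines=40):
        rng = np.random.default_rng(seed)
        lines = [f"cl{i}" for i in range(n_lines)]
        vals = rng.normal(0, 0.3, size=(6, n_lines))
        carriers = lines[: n_lines // 2]
        vals[0, : n_lines // 2] -= delta * 0.3
        m = make_matrix(vals, screens=lines)
        meta = make_meta(lines, cell_lines=lines, lineages=["t0"] * n_lines)
        cfe = pd.DataFrame({"CFE1": [1 if l in carriers else 0 for l in lines]},
                           index=lines)
        refs = ReferenceSets(cfe_matrix=cfe, cfe_tissue={"CFE1": "t0"})
        return m, meta, refs

    def test_planted_effect_recovered(self):
        m, meta, refs = self._cohort(delta=2.0)
        res = biomarker_associations(m, meta, refs, sgd_genes=list(m.gene_ids))
        hit = [r for r in res if r.gene == "g0" and r.cfe == "CFE1"][0]
        assert hit.fdr < 0.05
        assert hit.delta_fc < -1.0

    def test_identical_groups_give_null_statistics(self):
        m, meta, refs = self._cohort(delta=0.0)
        m.values[1, :] = 0.5  # identical in both groups
        res = biomarker_associations(m, meta, refs, sgd_genes=["g1"])
        assert res[0].t_statistic == pytest.approx(0.0, abs=1e-12) or np.isnan(
            res[0].t_statistic
        )
        assert res[0].delta_fc == pytest.approx(0.0, abs=1e-12)

    def test_small_groups_skipped(self):
        m, meta, refs = self._cohort(n_lines=40)
        refs.cfe_matrix["CFE1"] = [1, 1] + [0] * 38  # two carriers only
        res = biomarker_associations(m, meta, refs, sgd_genes=list(m.gene_ids))
        assert res == []

    def test_effect_size_matches_cohens_delta_formula(self):
        m, meta, refs = self._cohort(delta=1.0, seed=3)
        res = biomarker_associations(m, meta, refs, sgd_genes=["g0"])
        r = res[0]
        a = m.values[0, :20]
        b = m.values[0, 20:]
        pooled = np.sqrt((19 * a.var(ddof=1) + 19 * b.var(ddof=1)) / 38)
        assert r.delta_fc == pytest.approx((a.mean() - b.mean()) / pooled)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert r.t_statistic == pytest.approx(t) and r.p_value == pytest.approx(p)


class TestOncogeneBenchmark:
    def test_perfectly_separated_positives_give_auc_one(self):
        lines = [f"cl{i}" for i in range(10)]
        vals = np.zeros((2, 10))
        vals[0, :3] = -1.0  # positives most depleted (gene mean stays > -0.5)
        vals[0, 3:] = 0.1
        vals[1] = 0.0
        m = make_matrix(vals, genes=["onc", "other"], screens=lines)
        per, auc = oncogene_benchmark(m, {"onc": set(lines[:3])})
        assert auc == 1.0

    def test_shuffled_labels_give_half_auc(self):
        rng = np.random.default_rng(0)
        lines = [f"cl{i}" for i in range(200)]
        m = make_matrix(rng.normal(0, 0.3, size=(1, 200)), genes=["onc"], screens=lines)
        per, auc = oncogene_benchmark(m, {"onc": set(rng.choice(lines, 100, replace=False))})
        assert auc == pytest.approx(0.5, abs=0.1)

    def test_common_essential_oncogene_dropped(self):
        lines = [f"cl{i}" for i in range(6)]
        m = make_matrix(np.full((1, 6), -1.0), genes=["onc"], screens=lines)
        per, auc = oncogene_benchmark(m, {"onc": {"cl0"}})
        assert per == {} and np.isnan(auc)

    def test_per_oncogene_nnmd_matches_oracle(self):
        lines = ["a", "b", "c", "d", "e"]
        vals = np.array([[-1.2, -0.9, 0.0, 0.2, -0.2]])
        m = make_matrix(vals, genes=["onc"], screens=lines)
        per, auc = oncogene_benchmark(m, {"onc": {"a", "b"}})
        neg = np.array([0.0, 0.2, -0.2])
        expected = (np.mean([-1.2, -0.9]) - neg.mean()) / neg.std(ddof=1)
        assert per["onc"] == pytest.approx(expected)
        assert auc == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_auc_equals_mann_whitney_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = rng.integers(2, 8), rng.integers(2, 8)
        lines = [f"cl{i}" for i in range(n_pos + n_neg)]
        vals = rng.normal(0, 1, size=(1, len(lines)))
        m = make_matrix(vals, genes=["onc"], screens=lines)
        per, auc = oncogene_benchmark(m, {"onc": set(lines[:n_pos])})
        if np.isnan(auc):
            return
        u = stats.mannwhitneyu(-vals[0, :n_pos], -vals[0, n_pos:],
                               alternative="two-sided").statistic
        assert auc == pytest.approx(u / (n_pos * n_neg))


class TestGenePairRecovery:
    def _matrix(self, n_pairs=30, corr=0.9, seed=0, n_other=60, n_lines=50):
        rng = np.random.default_rng(seed)
        genes, rows, pairs = [], [], []
        for i in range(n_pairs):
            f = rng.normal(size=n_lines)
            g1, g2 = f + rng.normal(0, 0.3, n_lines), f + rng.normal(0, 0.3, n_lines)
            genes += [f"p{i}a", f"p{i}b"]
            rows += [g1, g2]
            pairs.append((f"p{i}a", f"p{i}b"))
        for i in range(n_other):
            genes.append(f"o{i}")
            rows.append(rng.normal(size=n_lines))
        m = make_matrix(np.array(rows), genes=genes,
                        screens=[f"cl{i}" for i in range(n_lines)])
        return m, pairs

    def test_planted_pairs_recovered(self):
        m, pairs = self._matrix()
        res = gene_pair_recovery(m, pairs, min_pairs=30, seed=0)
        assert res.n_recovered > 0.8 * res.n_tested

    def test_random_pairs_rarely_recovered(self):
        rng = np.random.default_rng(1)
        m, _ = self._matrix(n_pairs=0, n_other=80)
        fake = [(f"o{2*i}", f"o{2*i+1}") for i in range(40)]
        res = gene_pair_recovery(m, fake, min_pairs=40, seed=1, fdr=0.10)
        assert res.n_recovered <= 0.2 * res.n_tested

    def test_single_bootstrap_collapses_ci(self):
        m, pairs = self._matrix(n_pairs=10, n_other=30)
        res = gene_pair_recovery(m, pairs, min_pairs=10, n_bootstrap=1, seed=2)
        assert res.ci_low == res.ci_high == res.n_recovered

    def test_too_few_pairs_rejected(self):
        m, pairs = self._matrix(n_pairs=5, n_other=20)
        with pytest.raises(ValueError, match="related pairs"):
            gene_pair_recovery(m, pairs)
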