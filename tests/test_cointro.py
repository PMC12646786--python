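import dataclasses

import numpy as np
import pytest

import cytocline as cc
from cytocline import cointro
from conftest import simulate_bernoulli, simulate_binomial2


@pytest.fixture(scope="module")
def cp_reference():
    """Chloroplast reference cline fitted once for the whole module."""
    spec = cc.ClineModelSpec(center=0.43, width=0.05)
    data = simulate_bernoulli(spec, 300, seed=11)
    ref = cointro.build_reference(
        "chloroplast", data, variants=[("none", "none")], n_starts=8, seed=1
    )
    return spec, data, ref


def _fake_fit(center, width, cis=None):
    spec = cc.ClineModelSpec(center=center, width=width)
    return cc.ClineFit(spec=spec, loglik=-10.0, n_obs=100, converged=True,
                       boundary=False, seed=0,
                       support_intervals=cis or {})


def _ref(center_ci, width_ci):
    return cointro.ReferenceCline(
        label="chloroplast", fit=_fake_fit(np.mean(center_ci), np.mean(width_ci)),
        center_ci=center_ci, width_ci=width_ci,
    )


class TestClassifyGene:
    CP = _ref((0.40, 0.46), (0.03, 0.08))
    NUC = _ref((0.60, 0.76), (0.2, 0.4))

    def test_inside_cp_outside_nuc_is_co_introgressing(self):
        ocp, onuc, cls = cc.classify_gene(_fake_fit(0.43, 0.05), self.CP, self.NUC)
        assert (ocp, onuc, cls) == (True, False, "co_introgressing")

    def test_inside_both_is_ambiguous(self):
        wide_nuc = _ref((0.3, 0.6), (0.01, 0.5))
        _, _, cls = cc.classify_gene(_fake_fit(0.43, 0.05), self.CP, wide_nuc)
        assert cls == "ambiguous"

    def test_matching_nuclear_reference_is_independent(self):
        _, _, cls = cc.classify_gene(_fake_fit(0.68, 0.3), self.CP, self.NUC)
        assert cls == "independent"

    def test_non_converged_fit_unevaluable(self):
        bad = dataclasses.replace(_fake_fit(0.43, 0.05), converged=False)
        _, _, cls = cc.classify_gene(bad, self.CP, self.NUC)
        assert cls == "unevaluable"

    def test_interval_overlap_used_when_gene_has_support_intervals(self):
        # point estimate outside the cp CI but gene interval touches it
        fit = _fake_fit(0.47, 0.05, cis={"center": (0.44, 0.50), "width": (0.03, 0.08)})
        ocp, _, _ = cc.classify_gene(fit, self.CP, self.NUC)
        assert ocp is True

    def test_pure_function_repeated_calls_identical(self):
        fit = _fake_fit(0.43, 0.05)
        assert cc.classify_gene(fit, self.CP, self.NUC) == cc.classify_gene(
            fit, self.CP, self.NUC
        )


class TestConstrainedLRT:
    def test_interval_mode_inside_ci_gives_zero(self, cp_reference):
        spec, _, ref = cp_reference
        gd = simulate_binomial2(spec, 200, seed=21)
        gf = cc.fit_cline(gd, n_starts=6, seed=1)
        lo, hi = ref.center_ci
        if lo <= gf.spec.center <= hi:
            stat, p = cc.constrained_lrt(gd, gf, ref.center_ci, mode="interval")
            assert (stat, p) == (0.0, 1.0)

    def test_point_statistic_matches_fixed_center_refit(self, cp_reference):
        spec, _, ref = cp_reference
        gd = simulate_binomial2(spec, 150, seed=5)
        gf = cc.fit_cline(gd, n_starts=6, seed=1)
        c0 = ref.fit.spec.center
        stat, p = cc.constrained_lrt(gd, gf, ref.center_ci, reference_center=c0)
        refit = cc.fit_cline(gd, n_starts=6, seed=1, fixed_parameters={"center": c0})
        assert stat == pytest.approx(2 * (gf.loglik - refit.loglik), abs=1e-8)
        assert 0 <= stat and 0 < p <= 1

    def test_interval_statistic_matches_grid_constrained_oracle(self, cp_reference):
        spec, _, ref = cp_reference
        shifted = cc.ClineModelSpec(center=0.7, width=0.05)
        gd = simulate_binomial2(shifted, 80, seed=8)
        gf = cc.fit_cline(gd, n_starts=8, seed=1)
        stat, _ = cc.constrained_lrt(gd, gf, ref.center_ci, mode="interval", n_starts=8)
        lo, hi = ref.center_ci
        grid = max(
            cc.fit_cline(gd, n_starts=4, seed=1,
                         fixed_parameters={"center": c}).loglik
            for c in np.linspace(lo, hi, 40)
        )
        assert stat == pytest.approx(2 * (gf.loglik - grid), abs=1e-3)

    def test_power_against_distant_center(self, cp_reference):
        spec, _, ref = cp_reference
        distant = cc.ClineModelSpec(center=0.43 + 5 * 0.05, width=0.05)
        rejected = 0
        for s in range(20):
            gd = simulate_binomial2(distant, 300, seed=6000 + s)
            gf = cc.fit_cline(gd, n_starts=4, seed=s)
            _, p = cc.constrained_lrt(gd, gf, ref.center_ci,
                                      reference_center=ref.fit.spec.center,
                                      n_starts=4)
            rejected += p < 0.05
        assert rejected >= 18

    def test_empty_reference_interval_rejected(self, cp_reference):
        spec, _, _ = cp_reference
        gd = simulate_binomial2(spec, 50, seed=2)
        gf = cc.fit_cline(gd, n_starts=4, seed=1)
        with pytest.raises(ValueError):
            cc.constrained_lrt(gd, gf, (0.5, 0.4))


class TestGeneAncestry:
    def test_counts_from_matrix(self):
        m = cc.AncestryMatrix(
            ["I1_1", "I1_2", "I2_1", "I2_2"],
            [("chr1", 100), ("chr1", 150), ("chr1", 500)],
            np.array([[1, 1, 0], [1, 1, 0], [0, 1, 1], [0, 0, 1]]),
        )
        gene = cc.GeneAnnotation("g", "chr1", 90, 160, "+")
        d = cointro.gene_ancestry_data(m, gene, {"I1": 0.2, "I2": 0.8}, flank=0)
        # I1: both haplotypes majority-1 -> k=2; I2: majorities 0.5 and 0 -> k=1
        assert d.likelihood_kind == "binomial2"
        assert dict(zip(d.x, d.y)) == {0.2: 2.0, 0.8: 1.0}

    def test_flank_extends_gene_span(self):
        m = cc.AncestryMatrix(
            ["I1_1", "I1_2"], [("chr1", 95)], np.array([[1], [1]])
        )
        gene = cc.GeneAnnotation("g", "chr1", 150, 160, "+")
        with pytest.raises(ValueError):
            cointro.gene_ancestry_data(m, gene, {"I1": 0.5}, flank=10)
        d = cointro.gene_ancestry_data(m, gene, {"I1": 0.5}, flank=100)
        assert d.y.tolist() == [2.0]


class TestScan:
    def test_zero_genes_empty_summary(self, cp_reference):
        spec, cp_data, ref = cp_reference
        nuc = simulate_binomial2(cc.ClineModelSpec(center=0.68, width=0.3), 100, 1)
        nuc = cc.ClineData(nuc.x, nuc.y / 2.0, "gaussian")
        verdicts, summary = cc.scan({}, cp_data, nuc, n_starts=4, seed=1)
        assert verdicts == []
        assert summary.n_genes == summary.n_co_introgressing == 0

    def test_gene_order_invariance_and_count_partition(self, cp_reference):
        spec, cp_data, _ = cp_reference
        nuc_spec = cc.ClineModelSpec(center=0.68, width=0.3)
        genes = {
            "on_cp": simulate_binomial2(spec, 150, seed=31),
            "on_nuc": simulate_binomial2(nuc_spec, 150, seed=32),
            "mid": simulate_binomial2(cc.ClineModelSpec(center=0.55, width=0.2), 150, 33),
        }
        raw = simulate_binomial2(nuc_spec, 150, seed=34)
        nuc_data = cc.ClineData(raw.x, raw.y / 2.0, "gaussian")
        v1, s1 = cc.scan(genes, cp_data, nuc_data, n_starts=4, seed=1)
        rev = dict(reversed(list(genes.items())))
        v2, s2 = cc.scan(rev, cp_data, nuc_data, n_starts=4, seed=1)
        by_id_1 = {v.gene_id: v.classification for v in v1}
        by_id_2 = {v.gene_id: v.classification for v in v2}
        assert by_id_1 == by_id_2
        assert (s1.n_co_introgressing + s1.n_independent + s1.n_ambiguous
                + s1.n_unevaluable) == s1.n_genes
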