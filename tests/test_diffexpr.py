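import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rnlseq import diffexpr as de
from rnlseq import simulate as sim
from rnlseq.model import (
    ContrastSpec,
    CountMatrix,
    Denominator,
    Genotype,
    RunConfig,
    SampleMeta,
    Treatment,
    ValidationError,
)


def _cm(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(genes, samples, arr)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = _cm([[10, 10], [3, 3], [7, 7]])
        assert de.size_factors(cm) == pytest.approx([1.0, 1.0])

    def test_two_sample_doubling_toy(self):
        # every gene (c, 2c): geometric mean is c*sqrt(2), so the median
        # ratios are exactly (1/sqrt 2, sqrt 2)
        cm = _cm([[10, 20], [4, 8], [100, 200]])
        f = de.size_factors(cm)
        assert f == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])
        assert f[1] / f[0] == pytest.approx(2.0)

    def test_scale_equivariance_of_ratios(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(40, 3)) + 1
        f0 = de.size_factors(_cm(counts))
        scaled = counts.copy()
        scaled[:, 1] *= 10
        f1 = de.size_factors(_cm(scaled))
        ratio0 = f0 / f0[0]
        ratio1 = f1 / f1[0]
        assert ratio1[1] / ratio0[1] == pytest.approx(10.0)
        assert ratio1[2] / ratio0[2] == pytest.approx(1.0)

    def test_no_common_gene_advises_pseudo_reference(self):
        cm = _cm([[0, 5], [5, 0]])
        with pytest.raises(ValidationError, match="pseudo_reference"):
            de.size_factors(cm)
        assert de.size_factors(cm, pseudo_reference=True).shape == (2,)


def _replicate_design(n, treatment=Treatment.EV, time=4.0):
    return [
        SampleMeta(f"r{i}", Genotype.COL0, treatment, time, experiment=1, replicate=i + 1)
        for i in range(n)
    ]


class TestDispersion:
    def test_poisson_gene_near_zero(self):
        rng = np.random.default_rng(1)
        design = _replicate_design(20)
        counts = rng.poisson(100, size=(200, 20))
        cm = _cm(counts, samples=[s.sample_id for s in design])
        alpha = de.estimate_dispersion(cm, design, np.ones(20), shrink=0.0)
        assert np.median(alpha) < 0.01

    def test_nb_truth_recovered(self):
        rng = np.random.default_rng(2)
        design = _replicate_design(50)
        mean = np.full((500, 50), 200.0)
        counts = sim.nb_sample(rng, mean, np.full_like(mean, 0.1))
        cm = _cm(counts, samples=[s.sample_id for s in design])
        alpha = de.estimate_dispersion(cm, design, np.ones(50), shrink=0.0)
        assert 0.08 <= np.median(alpha) <= 0.12

    def test_constant_gene_zero(self):
        design = _replicate_design(4)
        cm = _cm(np.full((3, 4), 7), samples=[s.sample_id for s in design])
        alpha = de.estimate_dispersion(cm, design, np.ones(4), shrink=0.0)
        assert alpha == pytest.approx([0.0, 0.0, 0.0])

    def test_single_replicate_everywhere_rejected(self):
        cm = _cm([[1, 2]], samples=["a", "b"])
        design = [
            SampleMeta("a", Genotype.COL0, Treatment.EV, 4.0),
            SampleMeta("b", Genotype.COL0, Treatment.AVRRPS4, 4.0),
        ]
        with pytest.raises(ValidationError, match="2 replicates"):
            de.estimate_dispersion(cm, design, np.ones(2))


def _two_group_design():
    return [
        SampleMeta("a1", Genotype.COL0, Treatment.AVRRPS4, 4.0, replicate=1),
        SampleMeta("a2", Genotype.COL0, Treatment.AVRRPS4, 4.0, replicate=2),
        SampleMeta("b1", Genotype.COL0, Treatment.EV, 4.0, replicate=1),
        SampleMeta("b2", Genotype.COL0, Treatment.EV, 4.0, replicate=2),
    ]


_CONTRAST = ContrastSpec("rps4_vs_ev", Genotype.COL0, 4.0, Treatment.AVRRPS4)


class TestWald:
    def test_toy_agrees_with_poisson_glm_oracle(self):
        """2 vs 2 single-gene toy at alpha = 0, checked against an
        independently fitted Poisson GLM (statsmodels IRLS): the Wald p
        matches the GLM's Wald p closely, and lies within the known
        Wald-vs-LRT gap of the GLM's likelihood-ratio p."""
        import statsmodels.api as sm
        from scipy import stats as ss

        counts = np.array([[40, 44, 10, 12]])
        cm = _cm(counts, samples=["a1", "a2", "b1", "b2"])
        table = de.nb_wald_test(
            cm, _two_group_design(), np.ones(4), np.zeros(1), _CONTRAST
        )
        y = counts[0]
        X = np.column_stack([np.ones(4), [1, 1, 0, 0]])
        full = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        glm_wald_p = full.pvalues[1]
        assert abs(np.log10(table["p_value"].iloc[0]) - np.log10(glm_wald_p)) < 0.3
        null = sm.GLM(y, X[:, :1], family=sm.families.Poisson()).fit()
        lrt_p = ss.chi2.sf(2 * (full.llf - null.llf), df=1)
        # Wald is conservative relative to LRT at large effects; both
        # agree on order of magnitude
        assert abs(np.log10(table["p_value"].iloc[0]) - np.log10(lrt_p)) < 2.5
        assert table["log2_fc"].iloc[0] == pytest.approx(np.log2(42.5 / 11.5), abs=0.05)

    def test_identical_groups_give_null_fc(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(100, size=(200, 4))
        cm = _cm(counts, samples=["a1", "a2", "b1", "b2"])
        table = de.nb_wald_test(
            cm, _two_group_design(), np.ones(4), np.zeros(200), _CONTRAST
        )
        assert abs(table["log2_fc"].mean()) < 0.05

    def test_missing_condition_named_in_error(self):
        cm = _cm([[1, 2]], samples=["a1", "a2"])
        design = _two_group_design()[:2]
        with pytest.raises(ValidationError, match="denominator"):
            de.nb_wald_test(cm, design, np.ones(2), np.zeros(1), _CONTRAST)

    def test_low_count_genes_not_tested(self):
        counts = np.array([[100, 90, 110, 95], [1, 0, 2, 1]])
        cm = _cm(counts, samples=["a1", "a2", "b1", "b2"])
        table = de.nb_wald_test(
            cm, _two_group_design(), np.ones(4), np.zeros(2), _CONTRAST, min_count_filter=5
        )
        assert bool(table["tested"].iloc[0]) is True
        assert bool(table["tested"].iloc[1]) is False
        assert np.isnan(table["p_value"].iloc[1])

    def test_power_increases_with_effect_and_replicates(self):
        """Detection power is monotone in effect size and replication."""

        def power(log2_effect, n_rep, seed=0):
            rng = np.random.default_rng(seed)
            n_genes = 300
            design = []
            for trt in (Treatment.AVRRPS4, Treatment.EV):
                for i in range(n_rep):
                    design.append(
                        SampleMeta(f"{trt.value}{i}", Genotype.COL0, trt, 4.0, replicate=i + 1)
                    )
            mean = np.full((n_genes, 2 * n_rep), 100.0)
            mean[:, :n_rep] *= 2.0**log2_effect
            counts = sim.nb_sample(rng, mean, np.full_like(mean, 0.05))
            cm = _cm(counts, samples=[s.sample_id for s in design])
            table = de.nb_wald_test(cm, design, np.ones(2 * n_rep), np.full(n_genes, 0.05), _CONTRAST)
            return (table["p_value"] < 0.05).mean()

        powers = [power(e, 4) for e in (0.25, 0.5, 1.0)]
        assert powers[0] < powers[1] < powers[2]
        reps = [power(0.5, n) for n in (2, 4, 8)]
        assert reps[0] < reps[1] < reps[2]


class TestBH:
    def test_hand_computed_step_up(self):
        assert de.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert de.bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert de.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            de.bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=10))
    def test_matches_exhaustive_step_up_oracle(self, ps):
        # independent oracle: literal BH definition, adj_i = min over
        # j >= i (by p rank) of m * p_(j) / j, capped at 1
        m = len(ps)
        order = np.argsort(ps, kind="stable")
        sorted_p = np.asarray(ps)[order]
        oracle_sorted = [
            min(min(m * sorted_p[j] / (j + 1) for j in range(i, m)), 1.0)
            for i in range(m)
        ]
        oracle = np.empty(m)
        oracle[order] = oracle_sorted
        assert de.bh_adjust(ps) == pytest.approx(oracle)


class TestCallDegs:
    def _table(self, p_adj, lfc):
        return pd.DataFrame(
            {"p_adjusted": p_adj, "log2_fc": lfc},
            index=[f"g{i}" for i in range(len(p_adj))],
        )

    def test_threshold_boundaries_are_strict(self):
        table = self._table([0.04, 0.04, 0.05], [1.1, 1.0, 5.0])
        up, down = de.call_degs(table, RunConfig())
        assert up.genes == {"g0"}  # g1: FC not > 2; g2: p not < 0.05
        assert down.genes == frozenset()

    def test_down_direction(self):
        table = self._table([0.01, 0.01], [-1.5, -0.5])
        up, down = de.call_degs(table, RunConfig())
        assert down.genes == {"g0"} and up.genes == frozenset()

    def test_alpha_monotone(self):
        rng = np.random.default_rng(4)
        table = self._table(rng.uniform(0, 1, 100), rng.normal(0, 2, 100))
        small = de.call_degs(table, RunConfig(alpha_fdr=0.02))[0].genes
        large = de.call_degs(table, RunConfig(alpha_fdr=0.2))[0].genes
        assert small <= large


class TestVstZscore:
    def test_rows_standardized(self):
        rng = np.random.default_rng(5)
        cm = _cm(rng.poisson(100, size=(50, 6)))
        z = de.vst_zscore(cm, np.ones(6))
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        sds = z.std(axis=1, ddof=0)
        assert np.allclose(sds[sds > 0], 1, atol=1e-9)

    def test_constant_gene_maps_to_zero_row(self):
        cm = _cm([[5, 5, 5], [1, 2, 3]])
        z = de.vst_zscore(cm, np.ones(3))
        assert np.allclose(z.iloc[0], 0)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(50, size=(20, 5))
        f = rng.uniform(0.5, 2, 5)
        cm = _cm(counts)
        z = de.vst_zscore(cm, f)
        norm = counts / f[None, :]
        for i in range(20):
            assert (np.argsort(z.iloc[i].to_numpy(), kind="stable")
                    == np.argsort(norm[i], kind="stable")).all()
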