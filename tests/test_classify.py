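import itertools

import pytest
from hypothesis import given, strategies as st

from rnlseq import classify as rc
from rnlseq.diffexpr import DirectionalGeneSet
from rnlseq.model import (
    Genotype,
    RNLCategory,
    Treatment,
    ValidationError,
)


def _sv(col0, adr1, nrg1, helperless, gene="g1"):
    return rc.DEStatusVector(
        gene_id=gene,
        effector=Treatment.AVRRPS4,
        time_hpi=4.0,
        direction="up",
        de_flags={
            Genotype.COL0: col0,
            Genotype.ADR1_TRIPLE: adr1,
            Genotype.NRG1_DOUBLE: nrg1,
            Genotype.HELPERLESS: helperless,
        },
    )


class TestClassifyGene:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ((True, True, True, True), RNLCategory.RNL_INDEPENDENT),
            ((True, False, False, False), RNLCategory.SYNERGISTIC),
            ((True, True, True, False), RNLCategory.REDUNDANT),
            ((True, False, True, False), RNLCategory.ADR1_SPECIFIC),
            ((True, True, False, False), RNLCategory.NRG1_SPECIFIC),
            ((False, True, True, True), RNLCategory.NOT_ETI),
        ],
    )
    def test_named_profiles(self, flags, expected):
        assert rc.classify_gene(_sv(*flags)) is expected

    def test_exhaustive_truth_table(self):
        """All 16 flag combinations map to exactly one category;
        mutually exclusive and exhaustive over col0-DE genes."""
        seen = {}
        for flags in itertools.product([False, True], repeat=4):
            cat = rc.classify_gene(_sv(*flags))
            seen[flags] = cat
            if not flags[0]:
                assert cat is RNLCategory.NOT_ETI
            elif flags[3]:
                assert cat is RNLCategory.RNL_INDEPENDENT
            else:
                assert cat in {
                    RNLCategory.SYNERGISTIC,
                    RNLCategory.REDUNDANT,
                    RNLCategory.ADR1_SPECIFIC,
                    RNLCategory.NRG1_SPECIFIC,
                }
        assert len(seen) == 16
        # among col0=True, helperless=False rows each dependent category
        # appears exactly once per (adr1, nrg1) combination
        dep = [seen[(True, a, n, False)] for a in (False, True) for n in (False, True)]
        assert len(set(dep)) == 4

    def test_missing_flag_rejected(self):
        with pytest.raises(ValidationError, match="missing DE flags"):
            rc.DEStatusVector(
                "g", Treatment.AVRRPS4, 4.0, "up", {Genotype.COL0: True}
            )


def _dgs(genes, direction="up"):
    return DirectionalGeneSet(label="t", direction=direction, genes=frozenset(genes))


def _calls_for(effector=Treatment.AVRRPS4, time=4.0, **genotype_sets):
    """Build a deg_calls mapping from per-genotype up-sets (down empty)."""
    calls = {}
    for g in Genotype:
        up = genotype_sets.get(g.value, set())
        calls[(g, effector, time, "up")] = _dgs(up)
        calls[(g, effector, time, "down")] = _dgs(set(), "down")
    return calls


class TestSets:
    def test_pti_sets_missing_contrast_named(self):
        with pytest.raises(ValidationError, match="col0.*0.5"):
            rc.pti_sets({})

    def test_pti_sets_empty_set_is_not_error(self):
        calls = {}
        for g in Genotype:
            for t in (0.5, 4.0, 8.0):
                for d in ("up", "down"):
                    calls[(g, Treatment.EV, t, d)] = _dgs(set(), d)
        out = rc.pti_sets(calls)
        assert len(out) == 4 * 3 * 2
        assert all(len(s) == 0 for s in out.values())

    def test_eti_regulated_rejects_early_times(self):
        calls = _calls_for()
        for bad in (0.0, 0.5):
            with pytest.raises(ValidationError, match="4.0, 8.0"):
                rc.eti_regulated(calls, Genotype.COL0, Treatment.AVRRPS4, bad)

    def test_eti_up_down_disjoint(self):
        calls = _calls_for(col0={"g1", "g2"})
        up = rc.eti_regulated(calls, Genotype.COL0, Treatment.AVRRPS4, 4.0, "up")
        down = rc.eti_regulated(calls, Genotype.COL0, Treatment.AVRRPS4, 4.0, "down")
        assert not (up.genes & down.genes)

    def test_status_vectors_cover_col0_set(self):
        calls = _calls_for(
            col0={"a", "b", "c"}, adr1_triple={"a"}, nrg1_double={"a", "b"}
        )
        vecs = rc.status_vectors(calls, Treatment.AVRRPS4, 4.0, "up")
        assert [v.gene_id for v in vecs] == ["a", "b", "c"]
        cats = rc.assign_categories(vecs)
        assert cats["a"] is RNLCategory.REDUNDANT
        assert cats["b"] is RNLCategory.ADR1_SPECIFIC
        assert cats["c"] is RNLCategory.SYNERGISTIC

    def test_opposite_sign_in_mutant_treated_as_not_de(self):
        calls = _calls_for(col0={"a"})
        # gene a is DOWN in helperless while UP in col0
        calls[(Genotype.HELPERLESS, Treatment.AVRRPS4, 4.0, "down")] = _dgs({"a"}, "down")
        vecs = rc.status_vectors(calls, Treatment.AVRRPS4, 4.0, "up")
        assert rc.classify_gene(vecs[0]) is RNLCategory.SYNERGISTIC


class TestFractionReport:
    def test_study_scale_percentages(self):
        # 560 ETI genes of which 486 RNL-dependent: 86.8%; synergistic
        # 309 and redundant 17 of 486: 63.6% / 3.5%, shared 67.1%
        rep = rc.FractionReport(
            effector=Treatment.AVRRPS4,
            time_hpi=4.0,
            direction="up",
            n_eti=560,
            n_rnl_independent=74,
            n_synergistic=309,
            n_redundant=17,
            n_adr1_specific=119,
            n_nrg1_specific=41,
        )
        assert rep.n_rnl_dependent == 486
        assert rep.rnl_dependent_pct == 86.8
        assert rep.synergistic_pct == 63.6
        assert rep.redundant_pct == 3.5
        assert rep.shared_pct == 67.1

    def test_empty_assignments_undefined_percentages(self):
        rep = rc.fraction_report({}, Treatment.AVRRPS4, 4.0)
        assert rep.n_eti == 0
        assert rep.rnl_dependent_pct is None
        assert rep.shared_pct is None

    def test_not_eti_rejected(self):
        with pytest.raises(ValidationError, match="NOT_ETI"):
            rc.fraction_report({"g": RNLCategory.NOT_ETI}, Treatment.AVRRPS4, 4.0)

    @given(
        st.lists(
            st.sampled_from(
                [c for c in RNLCategory if c is not RNLCategory.NOT_ETI]
            ),
            max_size=50,
        )
    )
    def test_conservation(self, cats):
        """Category counts always sum to the ETI set size."""
        assignments = {f"g{i}": c for i, c in enumerate(cats)}
        rep = rc.fraction_report(assignments, Treatment.AVRRPT2, 8.0)
        assert rep.n_rnl_dependent + rep.n_rnl_independent == rep.n_eti == len(cats)
        if rep.n_rnl_dependent:
            assert rep.shared_pct + rep.specific_pct == pytest.approx(100.0, abs=0.11)


class TestVenn:
    def test_disjoint(self):
        out = rc.venn_counts([{"a", "b", "c"}, {"d", "e", "f", "g"}])
        assert out[(True, False)] == 3
        assert out[(False, True)] == 4
        assert out[(True, True)] == 0

    def test_identical(self):
        out = rc.venn_counts([{"a", "b"}, {"a", "b"}])
        assert out[(True, True)] == 2
        assert out[(True, False)] == out[(False, True)] == 0

    def test_wrong_arity(self):
        with pytest.raises(ValidationError):
            rc.venn_counts([{"a"}])

    @given(
        st.lists(
            st.sets(st.integers(min_value=0, max_value=20)), min_size=3, max_size=3
        )
    )
    def test_three_set_brute_force_oracle(self, sets):
        """Region counts equal exhaustive per-element membership counts."""
        out = rc.venn_counts(list(map(lambda s: set(map(str, s)), sets)))
        universe = set().union(*sets)
        for mask, n in out.items():
            expected = sum(
                1
                for el in universe
                if all((el in s) == m for s, m in zip(sets, mask))
            )
            assert n == expected
        assert sum(out.values()) == len(universe)
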