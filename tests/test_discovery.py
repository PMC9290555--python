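"""Mendelian-violation scan, stringent filters, spectrum counting."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dnmpipe import discovery
from dnmpipe.model import FILTER_NAMES, MUTATION_CLASSES, FilterConfig, Pedigree, SiteGenotypes
from dnmpipe.simulate import CohortSimConfig, simulate_trio_cohort

from .conftest import make_call, make_candidate


class TestClassify:
    def test_pyrimidine_reference_kept(self):
        assert discovery.classify_mutation("A", "G") == "A>G"
        assert discovery.classify_mutation("C", "T") == "C>T"

    def test_purine_reference_complemented(self):
        assert discovery.classify_mutation("G", "A") == "C>T"
        assert discovery.classify_mutation("T", "C") == "A>G"

    def test_all_twelve_pairs_fold_two_per_class(self):
        labels = [
            discovery.classify_mutation(r, a)
            for r, a in itertools.permutations("ACGT", 2)
        ]
        assert sorted(set(labels)) == sorted(MUTATION_CLASSES)
        for cls in MUTATION_CLASSES:
            assert labels.count(cls) == 2

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            discovery.classify_mutation("A", "A")
        with pytest.raises(ValueError):
            discovery.classify_mutation("N", "A")


def trio_site(child_gt, father_gt, mother_gt, extra=None, pos=100):
    calls = {
        "F": make_call(gt=father_gt, ad=(40, 0) if father_gt == "hom_ref" else (20, 20)),
        "M": make_call(gt=mother_gt, ad=(40, 0) if mother_gt == "hom_ref" else (20, 20)),
        "C": make_call(gt=child_gt),
    }
    if extra:
        calls.update(extra)
    return SiteGenotypes(chrom="1", pos=pos, ref="A", alt="G", calls=calls)


PED = Pedigree(
    individuals=["F", "M", "C", "U"],
    parent_map={"C": ("F", "M")},
)


class TestScan:
    def scan(self, sites, counters=None):
        return list(
            discovery.scan_mendelian_violations(sites, ("C", "F", "M"), PED, counters)
        )

    def test_violation_emitted(self):
        assert len(self.scan([trio_site("het", "hom_ref", "hom_ref")])) == 1

    def test_parent_carrier_not_emitted(self):
        assert self.scan([trio_site("het", "hom_ref", "het")]) == []
        assert self.scan([trio_site("hom_alt", "hom_ref", "hom_ref")]) == []

    def test_unrelated_carrier_flagged(self):
        extra = {"U": make_call(gt="het")}
        (cand,) = self.scan([trio_site("het", "hom_ref", "hom_ref", extra)])
        assert cand.nondescendant_carriers == 1
        verdicts = discovery.apply_stringent_filters(cand, FilterConfig()).filter_verdicts
        assert verdicts["nondescendant_absence"] == "fail"

    def test_missing_genotype_skipped_and_counted(self):
        counters = {}
        out = self.scan([trio_site("het", "missing", "hom_ref")], counters)
        assert out == []
        assert counters["missing_genotype"] == 1


class TestFilters:
    def test_all_pass(self):
        cand = discovery.apply_stringent_filters(make_candidate(), FilterConfig())
        assert cand.status == "high_confidence"
        assert set(cand.filter_verdicts) == set(FILTER_NAMES)

    def test_child_depth_19_fails_depth(self):
        cand = make_candidate(child=make_call(dp=19, ad=(9, 10), adf=5, adr=5))
        discovery.apply_stringent_filters(cand, FilterConfig())
        assert cand.filter_verdicts["depth"] == "fail"
        assert cand.status == "rejected"

    @pytest.mark.parametrize("dp,ok", [(20, True), (60, True), (19, False), (61, False)])
    def test_depth_bounds_inclusive(self, dp, ok):
        cand = make_candidate(child=make_call(dp=dp))
        discovery.apply_stringent_filters(cand, FilterConfig())
        assert (cand.filter_verdicts["depth"] == "pass") is ok

    def test_gq_strictly_above_threshold(self):
        cand = make_candidate(child=make_call(gq=70))
        discovery.apply_stringent_filters(cand, FilterConfig())
        assert cand.filter_verdicts["genotype_quality"] == "fail"

    def test_single_parent_alt_read_fails(self):
        cand = make_candidate(father=make_call(gt="hom_ref", ad=(39, 1), adf=0, adr=0))
        discovery.apply_stringent_filters(cand, FilterConfig())
        assert cand.filter_verdicts["parent_alt_reads"] == "fail"

    def test_allelic_balance_strict_bound(self):
        fail = make_candidate(child=make_call(dp=30, ad=(20, 10), adf=5, adr=5))
        discovery.apply_stringent_filters(fail, FilterConfig())
        assert fail.filter_verdicts["allelic_balance"] == "fail"  # 10/30 = 0.333
        ok = make_candidate(child=make_call(dp=30, ad=(18, 12), adf=6, adr=6))
        discovery.apply_stringent_filters(ok, FilterConfig())
        assert ok.filter_verdicts["allelic_balance"] == "pass"  # 12/30 = 0.4

    def test_single_strand_fails(self):
        cand = make_candidate(child=make_call(adf=20, adr=0))
        discovery.apply_stringent_filters(cand, FilterConfig())
        assert cand.filter_verdicts["both_strands"] == "fail"

    def test_missing_strand_fields_unevaluable(self):
        cand = make_candidate(child=make_call(adf=None, adr=None))
        discovery.apply_stringent_filters(cand, FilterConfig())
        assert cand.filter_verdicts["both_strands"] == "unevaluable"
        assert cand.status == "rejected"

    def test_all_verdicts_filled_despite_failures(self):
        cand = make_candidate(child=make_call(dp=5, gq=10, ad=(4, 1), adf=1, adr=0))
        discovery.apply_stringent_filters(cand, FilterConfig())
        assert all(v != "not_evaluated" for v in cand.filter_verdicts.values())


cand_strategy = st.builds(
    make_call,
    gt=st.just("het"),
    dp=st.integers(5, 80),
    gq=st.integers(0, 99),
    ad=st.tuples(st.integers(0, 40), st.integers(0, 40)),
    adf=st.integers(0, 20),
    adr=st.integers(0, 20),
)


class TestFilterProperties:
    @given(
        children=st.lists(cand_strategy, min_size=1, max_size=30),
        gq_lo=st.integers(40, 70),
        gq_hi=st.integers(71, 95),
        ab_lo=st.floats(0.1, 0.35),
        ab_hi=st.floats(0.36, 0.6),
        d_lo=st.tuples(st.integers(10, 20), st.integers(60, 70)),
        d_hi=st.tuples(st.integers(21, 30), st.integers(45, 59)),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_tightening_thresholds_never_gains_mutations(
        self, children, gq_lo, gq_hi, ab_lo, ab_hi, d_lo, d_hi
    ):
        """Raising GQ/AB cutoffs or narrowing depth bounds is monotone."""
        loose = FilterConfig(
            depth_min=d_lo[0], depth_max=d_lo[1], gq_min=gq_lo, allelic_balance_min=ab_lo
        )
        tight = FilterConfig(
            depth_min=d_hi[0], depth_max=d_hi[1], gq_min=gq_hi, allelic_balance_min=ab_hi
        )

        def n_pass(cfg):
            return sum(
                discovery.apply_stringent_filters(make_candidate(child=c), cfg).status
                == "high_confidence"
                for c in children
            )

        assert n_pass(tight) <= n_pass(loose)

    @given(cand_strategy)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_verdicts_independent_of_status(self, child):
        """Each verdict depends only on its own evidence, so re-evaluating a
        candidate gives the identical verdict map (order independence)."""
        a = discovery.apply_stringent_filters(make_candidate(child=child), FilterConfig())
        b = discovery.apply_stringent_filters(make_candidate(child=child), FilterConfig())
        assert a.filter_verdicts == b.filter_verdicts
        assert a.status == b.status


class TestNoiselessRecovery:
    def test_planted_dnms_recovered_exactly(self):
        """Zero noise, zero dropout: sensitivity 1, FDR 0."""
        cfg = CohortSimConfig(
            n_trios=5,
            genome_span_bp=400_000_000,
            depth_dispersion=None,
            even_allele_split=True,
            n_background_sites=300,
        )
        sim = simulate_trio_cohort(cfg, 17)
        found = set()
        for trio in sim.trios():
            for c in discovery.discover_dnms(sim.sites, trio, sim.ped):
                if c.status == "high_confidence":
                    found.add((c.trio, c.pos))
        truth = set(zip(sim.truth.trio, sim.truth.pos))
        assert found == truth
        assert len(truth) > 0


class TestSpectrumCounts:
    def test_empty_input(self):
        counts, tstv = discovery.spectrum_counts([])
        assert all(v == 0 for v in counts.values())
        assert tstv != tstv  # NaN

    def test_engineered_ts_tv_ratio(self):
        labels = ["A>G"] * 40 + ["C>T"] * 27 + ["A>C"] * 10 + ["A>T"] * 10 + ["C>A"] * 8 + ["C>G"] * 5
        counts, tstv = discovery.spectrum_counts(labels)
        assert sum(counts.values()) == 100
        assert tstv == pytest.approx(67 / 33, rel=1e-12)


class TestCompareSpectra:
    def test_identical_spectra_p_one(self):
        counts = {c: 20 for c in MUTATION_CLASSES}
        per_class, global_p = discovery.compare_spectra(counts, counts)
        assert global_p == pytest.approx(1.0)
        assert all(p == pytest.approx(1.0) for p in per_class.values())

    def test_per_class_matches_hand_computed_chi_square(self):
        """2x2 table (44 vs 189, 27 vs 73): chi-square without correction,
        checked against the closed form sum((O-E)^2/E)."""
        a = {"A>G": 44, "C>T": 189}
        b = {"A>G": 27, "C>T": 73}
        per_class, _ = discovery.compare_spectra(a, b)
        table = [[44, 189], [27, 73]]
        n = 44 + 189 + 27 + 73
        row = [233, 100]
        col = [71, 262]
        chi2 = sum(
            (table[i][j] - row[i] * col[j] / n) ** 2 / (row[i] * col[j] / n)
            for i in range(2)
            for j in range(2)
        )
        expected_p = stats.chi2.sf(chi2, df=1)
        assert per_class["A>G"] == pytest.approx(expected_p, rel=1e-10)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            discovery.compare_spectra({}, {"A>G": 3})
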