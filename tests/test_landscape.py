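"""Divergence computation, occupancy, profiles and composition tests."""

import math

import numpy as np
import pytest

from teeco.io_formats import GenomeLayout
from teeco.landscape import (
    AlignedPair,
    SaturationError,
    ancient_line_comparison,
    divergence_profile,
    kimura_cpg_divergence,
    occupancy_by_class,
    young_te_enrichment,
)

from conftest import fisher_two_sided_oracle, kimura_site_oracle, mk_te, random_aligned_pair


class TestKimura:
    def test_identical_pair_is_zero(self):
        assert kimura_cpg_divergence(AlignedPair("A" * 100, "A" * 100)) == 0.0

    def test_single_transition_ten_sites(self):
        pair = AlignedPair("AAAAAAAAAA", "GAAAAAAAAA")
        want = -50 * math.log(0.8)  # p=0.1, q=0
        assert kimura_cpg_divergence(pair, cpg_correction=False) == pytest.approx(want, abs=1e-12)
        assert want == pytest.approx(11.157177565710485)

    def test_transition_at_cpg_downweighted(self):
        pair = AlignedPair("ACGA", "ATGA")
        got = kimura_cpg_divergence(pair)
        assert got == pytest.approx(kimura_site_oracle("ACGA", "ATGA"), abs=1e-12)
        # 1/10 weighting: p = 0.1/4
        assert got == pytest.approx(-50 * math.log(1 - 2 * 0.025), abs=1e-12)
        # without correction the transition counts fully
        assert kimura_cpg_divergence(pair, cpg_correction=False) == pytest.approx(
            -50 * math.log(1 - 2 * 0.25), abs=1e-12
        )

    def test_double_cpg_transition_counts_once(self):
        # consensus CG -> copy TA would be transversions; use CG -> TG + CA
        pair = AlignedPair("ACGAAAAAAA", "ATAAAAAAAA")  # C->T ts, G->A ts at one CpG
        got = kimura_cpg_divergence(pair)
        assert got == pytest.approx(kimura_site_oracle("ACGAAAAAAA", "ATAAAAAAAA"), abs=1e-12)
        # one full transition out of 10 sites
        assert got == pytest.approx(-50 * math.log(1 - 2 * 0.1), abs=1e-12)

    def test_matches_site_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            cons, copy = random_aligned_pair(rng)
            got = kimura_cpg_divergence(AlignedPair(cons, copy))
            want = kimura_site_oracle(cons, copy)
            assert abs(got - want) < 1e-9

    def test_reduces_to_k2p_without_correction(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            cons, copy = random_aligned_pair(rng)
            comparable = [
                (a, b) for a, b in zip(cons, copy) if a in "ACGT" and b in "ACGT"
            ]
            n = len(comparable)
            ts = sum(1 for a, b in comparable if a != b and a + b in {"AG", "GA", "CT", "TC"})
            tv = sum(1 for a, b in comparable if a != b and a + b not in {"AG", "GA", "CT", "TC"})
            p, q = ts / n, tv / n
            want = -50 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q))
            got = kimura_cpg_divergence(AlignedPair(cons, copy), cpg_correction=False)
            assert abs(got - want) < 1e-9

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            kimura_cpg_divergence(AlignedPair("AAAA", "GGGG"), cpg_correction=False)

    def test_bad_pairs_rejected(self):
        with pytest.raises(ValueError):
            AlignedPair("ACGT", "ACG")
        with pytest.raises(ValueError):
            AlignedPair("ACGX", "ACGT")
        with pytest.raises(ValueError):
            kimura_cpg_divergence(AlignedPair("----", "ACGT"))


class TestOccupancy:
    def test_percent_of_genome(self, small_layout):
        anns = [
            mk_te(element_id=0, start=0, end=60_000),
            mk_te(element_id=1, start=100_000, end=150_000),
            mk_te(element_id=2, chrom="chr2", start=0, end=55_000),
        ]
        occ = occupancy_by_class(anns, small_layout)
        assert occ["LTR"] == (165_000, pytest.approx(11.0))

    def test_empty_annotations(self, small_layout):
        assert occupancy_by_class([], small_layout) == {}

    def test_abutting_intervals_not_double_counted(self, small_layout):
        anns = [
            mk_te(element_id=0, start=0, end=100),
            mk_te(element_id=1, start=100, end=200),
            mk_te(element_id=2, start=150, end=180),  # nested: union unchanged
        ]
        occ = occupancy_by_class(anns, small_layout)
        assert occ["LTR"][0] == 200

    def test_order_invariance(self, small_layout, rodentlike_resolved):
        fwd = occupancy_by_class(rodentlike_resolved, GenomeLayout(
            chromosomes=tuple((f"chr{i+1}", 2_000_000) for i in range(5))))
        rev = occupancy_by_class(rodentlike_resolved[::-1], GenomeLayout(
            chromosomes=tuple((f"chr{i+1}", 2_000_000) for i in range(5))))
        assert fwd == rev


class TestDivergenceProfile:
    def test_element_assigned_to_containing_bin(self, small_layout):
        prof = divergence_profile([mk_te(end=1000, divergence_pct=0.5)], small_layout)
        assert prof.occupancy_bp["LTR"][0] == 1000
        assert prof.occupancy_bp["LTR"][1:].sum() == 0

    def test_bin_edge_goes_to_upper_bin(self, small_layout):
        prof = divergence_profile([mk_te(end=1000, divergence_pct=1.0)], small_layout)
        assert prof.occupancy_bp["LTR"][0] == 0
        assert prof.occupancy_bp["LTR"][1] == 1000

    def test_overflow_bin(self, small_layout):
        prof = divergence_profile([mk_te(end=1000, divergence_pct=75.0)], small_layout)
        assert prof.occupancy_bp["LTR"][-1] == 1000

    def test_mass_conservation(self, small_layout):
        rng = np.random.default_rng(3)
        anns = []
        pos = 0
        for i in range(300):
            length = int(rng.integers(50, 2000))
            anns.append(
                mk_te(
                    element_id=i, start=pos, end=pos + length,
                    te_class=str(rng.choice(["LINE", "SINE", "LTR", "DNA"])),
                    divergence_pct=float(rng.uniform(0, 80)),
                )
            )
            pos += length + 10
        prof = divergence_profile(anns, small_layout)
        per_class_total = {}
        for a in anns:
            per_class_total[a.te_class] = per_class_total.get(a.te_class, 0) + a.length
        for cls, total in per_class_total.items():
            assert prof.occupancy_bp[cls].sum() == total


class TestCompositionTests:
    def test_young_te_table_matches_enumeration(self):
        # 3 young LTR, 1 old LTR, 1 young LINE, 3 old LINE
        anns = (
            [mk_te(element_id=i, start=i * 200, end=i * 200 + 100, divergence_pct=0.5) for i in range(3)]
            + [mk_te(element_id=3, start=700, end=800, divergence_pct=9.0)]
            + [mk_te(element_id=4, start=900, end=1000, te_class="LINE", divergence_pct=0.5)]
            + [
                mk_te(element_id=5 + i, start=1100 + i * 200, end=1200 + i * 200,
                      te_class="LINE", divergence_pct=9.0)
                for i in range(3)
            ]
        )
        res = young_te_enrichment(anns, young_threshold=1.0, focal_class="LTR")
        assert res.p == pytest.approx(fisher_two_sided_oracle(3, 1, 1, 3), abs=1e-12)
        assert res.p == pytest.approx(34 / 70, abs=1e-12)

    def test_identical_composition_p_one(self):
        anns = [
            mk_te(element_id=0, start=0, end=100, divergence_pct=0.5),
            mk_te(element_id=1, start=200, end=300, divergence_pct=5.0),
            mk_te(element_id=2, start=400, end=500, te_class="LINE", divergence_pct=0.5),
            mk_te(element_id=3, start=600, end=700, te_class="LINE", divergence_pct=5.0),
        ]
        assert young_te_enrichment(anns).p == 1.0

    def test_empty_focal_class_errors(self):
        with pytest.raises(ValueError):
            young_te_enrichment([mk_te(te_class="LINE")], focal_class="LTR")

    def test_ancient_line_comparison(self):
        def lines(n_ancient, n_other, offset=0):
            out = []
            for i in range(n_ancient):
                out.append(mk_te(element_id=offset + i, start=i * 300, end=i * 300 + 200,
                                 te_class="LINE", subfamily="L2_anc"))
            for i in range(n_other):
                out.append(mk_te(element_id=offset + 1000 + i, start=100_000 + i * 300,
                                 end=100_000 + i * 300 + 200, te_class="LINE", subfamily="L1_new"))
            return out

        res = ancient_line_comparison(lines(16, 84), lines(9, 91), {"L2_anc"})
        assert res.counts_a == (16, 84) and res.counts_b == (9, 91)
        assert res.prop_bp_a == pytest.approx(0.16)
        assert res.p == pytest.approx(fisher_two_sided_oracle(16, 84, 9, 91), abs=1e-12)

    def test_ancient_labels_empty_warns(self):
        anns = [mk_te(te_class="LINE")]
        with pytest.warns(UserWarning):
            res = ancient_line_comparison(anns, anns, set())
        assert math.isnan(res.p)
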