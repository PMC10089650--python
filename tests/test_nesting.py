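"""Interruption detection by consensus conjoining, and its permutation null."""

import dataclasses

import numpy as np
import pytest

from teeco.io_formats import GenomeLayout, resolve_overlaps
from teeco.nesting import detect_interruptions, flanked_regions, permutation_erv_in_line
from teeco.synthetic_data import generate, null_config, planted_interruption_config

from conftest import mk_te


def _triple(cons_b=(2001, 6100), strand_b="+", erv_span=(3000, 8000), chrom="chr1"):
    """fragA [1000,3000) cons 1-2000 (+) | ERV | fragB [8000,12100)."""
    frag_a = mk_te(element_id=0, chrom=chrom, start=1000, end=3000, te_class="LINE",
                   subfamily="L1X", superfamily="L1", cons_start=1, cons_end=2000,
                   cons_remaining=4100)
    erv = mk_te(element_id=1, chrom=chrom, start=erv_span[0], end=erv_span[1],
                subfamily="ERVa", cons_start=1, cons_end=erv_span[1] - erv_span[0])
    frag_b = mk_te(element_id=2, chrom=chrom, start=8000, end=8000 + (cons_b[1] - cons_b[0] + 1),
                   strand=strand_b, te_class="LINE", subfamily="L1X", superfamily="L1",
                   cons_start=cons_b[0], cons_end=cons_b[1], cons_remaining=6100 - cons_b[1])
    return [frag_a, erv, frag_b]


class TestDetect:
    def test_forced_full_length_call(self):
        calls = detect_interruptions(_triple())
        assert len(calls) == 1
        c = calls[0]
        assert c.classification == "full_length"
        assert c.cons_gap_bp == [0]
        assert c.conjoined_cons_len == 6100
        assert c.erv_ids == [1]
        assert c.span == (1000, 12100)

    def test_consensus_gap_beyond_tolerance(self):
        assert detect_interruptions(_triple(cons_b=(2601, 6100))) == []

    def test_small_consensus_gap_within_tolerance(self):
        calls = detect_interruptions(_triple(cons_b=(2051, 6100)))
        assert len(calls) == 1 and calls[0].cons_gap_bp == [50]

    def test_strand_mismatch(self):
        assert detect_interruptions(_triple(strand_b="-")) == []

    def test_minus_strand_pair_conjoins_mirrored(self):
        # genomically first fragment carries the consensus tail on minus strand
        frag_a = mk_te(element_id=0, start=1000, end=5100, strand="-", te_class="LINE",
                       subfamily="L1X", cons_start=2001, cons_end=6100, cons_remaining=0)
        erv = mk_te(element_id=1, start=5100, end=9000, subfamily="ERVa")
        frag_b = mk_te(element_id=2, start=9000, end=11000, strand="-", te_class="LINE",
                       subfamily="L1X", cons_start=1, cons_end=2000, cons_remaining=4100)
        calls = detect_interruptions([frag_a, erv, frag_b])
        assert len(calls) == 1 and calls[0].strand == "-"

    def test_intact_line_no_call(self):
        line = mk_te(element_id=0, start=1000, end=7100, te_class="LINE",
                     subfamily="L1X", cons_start=1, cons_end=6100)
        assert detect_interruptions([line]) == []

    def test_unannotated_junction_gap_tolerance(self):
        anns = _triple(erv_span=(3060, 8000))  # 60 bp unannotated at left junction
        assert detect_interruptions(anns, genomic_gap_tol=50) == []
        assert len(detect_interruptions(anns, genomic_gap_tol=100)) == 1

    def test_non_erv_between_blocks_call(self):
        anns = _triple(erv_span=(3000, 7000))
        sine = mk_te(element_id=9, start=7000, end=8000, te_class="SINE", subfamily="B1")
        anns = sorted(anns + [sine], key=lambda a: (a.chrom, a.start))
        assert detect_interruptions(anns) == []

    def test_strict_excludes_three_fragment_chains(self):
        # L1 split twice: A | ERV | B | ERV | C, all conjoining
        a = mk_te(element_id=0, start=0, end=2000, te_class="LINE", subfamily="L1X",
                  cons_start=1, cons_end=2000, cons_remaining=4100)
        e1 = mk_te(element_id=1, start=2000, end=4000, subfamily="ERVa")
        b = mk_te(element_id=2, start=4000, end=6000, te_class="LINE", subfamily="L1X",
                  cons_start=2001, cons_end=4000, cons_remaining=2100)
        e2 = mk_te(element_id=3, start=6000, end=8000, subfamily="ERVb")
        c = mk_te(element_id=4, start=8000, end=10100, te_class="LINE", subfamily="L1X",
                  cons_start=4001, cons_end=6100, cons_remaining=0)
        anns = [a, e1, b, e2, c]
        assert detect_interruptions(anns, strict=True) == []
        relaxed = detect_interruptions(anns, strict=False)
        assert len(relaxed) == 1
        assert relaxed[0].n_fragments == 3
        assert relaxed[0].erv_ids == [1, 3]
        assert relaxed[0].classification == "full_length"

    def test_relaxed_admits_fragmented_reconstruction(self):
        anns = _triple(cons_b=(2001, 3000))  # united span 3000 bp < 5000
        assert detect_interruptions(anns, strict=True) == []
        relaxed = detect_interruptions(anns, strict=False)
        assert len(relaxed) == 1 and relaxed[0].classification == "fragmented"

    def test_unsorted_input_errors(self):
        anns = _triple()[::-1]
        with pytest.raises(ValueError, match="sorted"):
            detect_interruptions(anns)

    def test_planted_truth_recovery_small(self):
        ds = generate(planted_interruption_config(seed=5, n_interruptions=10))
        anns = resolve_overlaps(ds.annotations)
        calls = detect_interruptions(anns)
        want = {(t["chrom"], tuple(t["span"])) for t in ds.truth.interruptions}
        got = {(c.chrom, c.span) for c in calls}
        assert got == want

    def test_relaxed_count_at_least_strict(self, rodentlike_resolved):
        strict = detect_interruptions(rodentlike_resolved, strict=True)
        relaxed = detect_interruptions(rodentlike_resolved, strict=False)
        assert len(relaxed) >= len(strict)


class TestFlankedRegions:
    def test_regions_between_same_subfamily_pairs(self):
        anns = sorted(_triple(), key=lambda a: a.start)
        regions = flanked_regions(anns, exclude_subfamily="ERVa")
        assert regions["chr1"] == [(3000, 8000)]

    def test_conjoining_requirement_filters(self):
        anns = _triple(cons_b=(2601, 6100))
        assert flanked_regions(anns, exclude_subfamily="ERVa")["chr1"] == [(3000, 8000)]
        assert flanked_regions(anns, exclude_subfamily="ERVa", require_conjoining=True)["chr1"] == []


class TestPermutation:
    def test_planted_subfamily_maximal_enrichment(self):
        layout = GenomeLayout(chromosomes=(("chr1", 1_000_000),))
        anns = []
        pos = 1000
        for i in range(12):
            # alternate strands so consecutive triples never flank each other
            st = "+" if i % 2 == 0 else "-"
            anns += [
                mk_te(element_id=3 * i, start=pos, end=pos + 2000, strand=st,
                      te_class="LINE", subfamily="L1X", cons_start=1, cons_end=2000,
                      cons_remaining=4100),
                mk_te(element_id=3 * i + 1, start=pos + 2000, end=pos + 2600, subfamily="ERVin"),
                mk_te(element_id=3 * i + 2, start=pos + 2600, end=pos + 6700, strand=st,
                      te_class="LINE", subfamily="L1X", cons_start=2001, cons_end=6100,
                      cons_remaining=0),
            ]
            pos += 50_000
        res = permutation_erv_in_line(anns, layout, n_perm=200, seed=1)
        (r,) = [x for x in res if x.unit == "ERVin"]
        assert r.observed == 12
        assert r.p == pytest.approx(1 / 201)
        assert r.ratio > 5

    def test_invariant_to_input_order(self):
        ds = generate(planted_interruption_config(seed=2, n_interruptions=5))
        anns = resolve_overlaps(ds.annotations)
        layout = ds.layout
        res_a = permutation_erv_in_line(anns, layout, n_perm=100, seed=9)
        rng = np.random.default_rng(0)
        shuffled = list(anns)
        rng.shuffle(shuffled)
        shuffled.sort(key=lambda a: (a.chrom, a.start, a.end))
        res_b = permutation_erv_in_line(shuffled, layout, n_perm=100, seed=9)
        assert [dataclasses.asdict(r) for r in res_a] == [dataclasses.asdict(r) for r in res_b]

    def test_n_perm_zero_errors(self, small_layout):
        with pytest.raises(ValueError):
            permutation_erv_in_line([mk_te()], small_layout, n_perm=0, seed=1)
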