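"""Detection of ERV insertions interrupting LINEs, with permutation nulls.

When an ERV inserts into an intact LINE it splits the host into two (or
more) fragments that are adjacent on the chromosome, carry the same
subfamily and strand, and whose consensus coordinates conjoin: the second
fragment resumes on the subfamily consensus where the first one stopped.
Detection therefore scans each chromosome for LINE fragment pairs separated
only by ERV sequence, requires consensus conjoining within a small
tolerance, and classifies the reconstruction as full length when the united
consensus span exceeds 5,000 bp.

Strict mode mirrors the conservative census: exactly two fragments, nothing
but ERV sequence between them, full-length reconstruction. Relaxed mode
chains more than two fragments and admits fragmented reconstructions.

The per-subfamily enrichment test asks whether a given ERV subfamily sits
between same-subfamily LINE fragments more often than uniform re-placement
of its elements (per chromosome, lengths preserved) would produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import IntervalIndex, uncovered_runs
from .io_formats import GenomeLayout, TEAnnotation
from .stats import EnrichmentResult, bonferroni, permutation_pvalue, place_uniform, rng_for

FULL_LENGTH_MIN_BP = 5000


@dataclass
class InterruptionCall:
    """A reconstructed LINE split by one or more interleaving ERV insertions."""

    line_subfamily: str
    line_fragment_ids: list[int]
    erv_ids: list[int]
    chrom: str
    span: tuple[int, int]
    conjoined_cons_len: int
    cons_gap_bp: list[int]  # signed consensus gap at each junction
    n_fragments: int
    classification: str  # {full_length, fragmented}
    strand: str = "+"


def _check_sorted(annotations: Sequence[TEAnnotation]) -> None:
    for a, b in zip(annotations, annotations[1:]):
        if (a.chrom, a.start) > (b.chrom, b.start):
            raise ValueError("annotations must be sorted by (chrom, start)")


def _cons_gap(a: TEAnnotation, b: TEAnnotation) -> int:
    """Signed consensus gap between genomically successive fragments a then b.

    0 means b resumes exactly where a stopped. On the minus strand the
    genomic order is the mirror of the consensus order.
    """
    if a.strand == "+":
        return b.cons_start - a.cons_end - 1
    return a.cons_start - b.cons_end - 1


def _junctions_covered(
    a: TEAnnotation, b: TEAnnotation, between: Sequence[TEAnnotation], genomic_gap_tol: int
) -> bool:
    """Is [a.end, b.start) covered by the intervening elements, allowing up to
    ``genomic_gap_tol`` unannotated bp per junction run?"""
    runs = uncovered_runs((a.end, b.start), [(x.start, x.end) for x in between])
    return all(e - s <= genomic_gap_tol for s, e in runs)


def detect_interruptions(
    annotations: Sequence[TEAnnotation],
    cons_gap_tol: int = 100,
    genomic_gap_tol: int = 50,
    strict: bool = True,
    full_length_min_bp: int = FULL_LENGTH_MIN_BP,
) -> list[InterruptionCall]:
    """Find LINEs split by ERV insertions via consensus-coordinate conjoining.

    Input must be sorted by (chrom, start) and overlap-resolved. In strict
    mode a call requires exactly two same-subfamily, same-strand LINE
    fragments with only ERV annotations between them, consensus conjoining
    within ``cons_gap_tol``, every unannotated junction run at most
    ``genomic_gap_tol`` bp, and a united consensus span above
    ``full_length_min_bp``. Relaxed mode chains any number of fragments and
    also reports fragmented (short) reconstructions.
    """
    _check_sorted(annotations)
    calls: list[InterruptionCall] = []
    n = len(annotations)
    used_as_start: set[int] = set()

    i = 0
    while i < n:
        a = annotations[i]
        if a.te_class != "LINE" or i in used_as_start:
            i += 1
            continue
        chain = [i]
        j = i
        while True:
            # scan forward from fragment j for the next non-ERV annotation
            k = j + 1
            between: list[int] = []
            while (
                k < n
                and annotations[k].chrom == annotations[j].chrom
                and annotations[k].is_erv
            ):
                between.append(k)
                k += 1
            if (
                k >= n
                or annotations[k].chrom != annotations[j].chrom
                or not between
            ):
                break
            b = annotations[k]
            aj = annotations[j]
            if (
                b.te_class != "LINE"
                or b.subfamily != aj.subfamily
                or b.strand != aj.strand
                or abs(_cons_gap(aj, b)) > cons_gap_tol
                or not _junctions_covered(aj, b, [annotations[x] for x in between], genomic_gap_tol)
            ):
                break
            chain.append(k)
            j = k

        if len(chain) >= 2:
            frags = [annotations[x] for x in chain]
            erv_ids = [
                annotations[x].element_id
                for x in range(chain[0] + 1, chain[-1])
                if annotations[x].is_erv
            ]
            cons_lo = min(f.cons_start for f in frags)
            cons_hi = max(f.cons_end for f in frags)
            conjoined = cons_hi - cons_lo + 1
            classification = "full_length" if conjoined > full_length_min_bp else "fragmented"
            # strict census: exactly two fragments and a full-length
            # reconstruction; longer chains are excluded outright
            keep = (
                classification == "full_length" and len(chain) == 2
                if strict
                else True
            )
            if keep:
                calls.append(
                    InterruptionCall(
                        line_subfamily=frags[0].subfamily,
                        line_fragment_ids=[f.element_id for f in frags],
                        erv_ids=erv_ids,
                        chrom=frags[0].chrom,
                        span=(frags[0].start, frags[-1].end),
                        conjoined_cons_len=conjoined,
                        cons_gap_bp=[_cons_gap(x, y) for x, y in zip(frags, frags[1:])],
                        n_fragments=len(frags),
                        classification=classification,
                        strand=frags[0].strand,
                    )
                )
                used_as_start.update(chain[1:])
        i += 1
    return calls


# ---------------------------------------------------------------------------
# Permutation enrichment of ERV subfamilies inside LINEs
# ---------------------------------------------------------------------------


def flanked_regions(
    annotations: Sequence[TEAnnotation],
    exclude_subfamily: str | None = None,
    require_conjoining: bool = False,
    cons_gap_tol: int = 100,
) -> dict[str, list[tuple[int, int]]]:
    """Genomic gaps bounded by same-subfamily, same-strand LINE fragments.

    A region is the interval between two successive non-ERV annotations that
    are both LINE fragments of one subfamily and strand; any annotations
    between them must be ERVs (elements of ``exclude_subfamily`` are ignored
    entirely, so the region set is fixed while that subfamily is shuffled).
    With ``require_conjoining`` the flanking pair must also conjoin in
    consensus coordinates — the stricter census criterion.
    """
    regions: dict[str, list[tuple[int, int]]] = {}
    by_chrom: dict[str, list[TEAnnotation]] = {}
    for a in annotations:
        if exclude_subfamily is not None and a.subfamily == exclude_subfamily:
            continue
        by_chrom.setdefault(a.chrom, []).append(a)
    for chrom, anns in by_chrom.items():
        non_erv = [a for a in anns if not a.is_erv]
        out = []
        for u, v in zip(non_erv, non_erv[1:]):
            if (
                u.te_class == "LINE"
                and v.te_class == "LINE"
                and u.subfamily == v.subfamily
                and u.strand == v.strand
                and v.start > u.end
            ):
                if require_conjoining and abs(_cons_gap(u, v)) > cons_gap_tol:
                    continue
                out.append((u.end, v.start))
        regions[chrom] = out
    return regions


def permutation_erv_in_line(
    annotations: Sequence[TEAnnotation],
    layout: GenomeLayout,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
    require_conjoining: bool = False,
    cons_gap_tol: int = 100,
) -> list[EnrichmentResult]:
    """Per-ERV-subfamily enrichment of elements flanked by same-subfamily LINEs.

    Observed count: elements of the subfamily lying entirely within a flanked
    region (see :func:`flanked_regions`). Null: the subfamily's elements are
    re-placed uniformly per chromosome (lengths preserved, other annotations
    fixed, overlaps permitted), ``n_perm`` times. p = (r+1)/(n_perm+1) for
    r = #{null >= observed}; q = Bonferroni over tested subfamilies; ratio =
    observed / mean(null). Child RNGs are derived from (seed, subfamily), so
    results are independent of input order.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _check_sorted(annotations)
    lengths = layout.lengths
    subfams = sorted({a.subfamily for a in annotations if a.is_erv})
    results: list[EnrichmentResult] = []
    for sub in subfams:
        focal = [a for a in annotations if a.subfamily == sub]
        if not focal:
            continue
        regions = flanked_regions(
            annotations, exclude_subfamily=sub,
            require_conjoining=require_conjoining, cons_gap_tol=cons_gap_tol,
        )
        idx = {chrom: IntervalIndex(rs) for chrom, rs in regions.items()}

        observed = 0
        for a in focal:
            ii = idx.get(a.chrom)
            if ii is not None and len(ii) and bool(ii.contains(a.start, a.end)):
                observed += 1

        rng = rng_for(seed, "erv_in_line", sub)
        null = np.zeros(n_perm, dtype=np.int64)
        by_chrom: dict[str, list[TEAnnotation]] = {}
        for a in focal:
            by_chrom.setdefault(a.chrom, []).append(a)
        for chrom, anns in sorted(by_chrom.items()):
            lens = np.array([a.length for a in anns], dtype=np.int64)
            starts = place_uniform(rng, lens, lengths[chrom], n_perm)
            ii = idx.get(chrom)
            if ii is None or len(ii) == 0:
                continue
            null += ii.contains(starts, starts + lens[None, :]).sum(axis=1)

        p, mean, ratio = permutation_pvalue(observed, null)
        results.append(
            EnrichmentResult(
                unit=sub, observed=observed, expected_mean=mean, ratio=ratio,
                p=p, test="permutation",
                extra={"n_elements": len(focal), "alpha": alpha},
            )
        )
    qs = bonferroni([r.p for r in results]) if results else []
    for r, q in zip(results, qs):
        r.q = float(q)
    return results
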