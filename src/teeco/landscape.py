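"""Genome occupancy, divergence-binned TE landscapes and composition tests.

The landscape view of a repeat annotation is the amount of sequence each TE
class contributes as a function of the elements' divergence from their
subfamily consensus — young (low-divergence) bins reflect recent activity,
old bins ancient accumulation. Divergence is the Kimura two-parameter
distance with the repeat-annotation CpG adjustment: transitions at consensus
CpG dinucleotides are hypermutable and are down-weighted to 1/10, and a CpG
whose two positions both carry transitions contributes a single transition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GenomeLayout, TEAnnotation, class_occupancy_bp
from .stats import EnrichmentResult, fisher_exact_two_sided

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_VALID = set("ACGTN-")


class SaturationError(ValueError):
    """Divergence undefined: the Kimura log argument is non-positive."""


@dataclass(frozen=True)
class AlignedPair:
    """A gapped consensus/copy alignment over {A,C,G,T,N,-}."""

    consensus_seq: str
    copy_seq: str

    def __post_init__(self):
        a, b = self.consensus_seq.upper(), self.copy_seq.upper()
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        if set(a) - _VALID or set(b) - _VALID:
            raise ValueError("sequences restricted to A,C,G,T,N,-")
        object.__setattr__(self, "consensus_seq", a)
        object.__setattr__(self, "copy_seq", b)


def _consensus_cpg_pairs(consensus: str) -> list[tuple[int, int]]:
    """Alignment-column index pairs (i, j) forming CpG on the ungapped consensus."""
    pairs = []
    prev_c: int | None = None
    for i, base in enumerate(consensus):
        if base == "-":
            continue
        if prev_c is not None and base == "G":
            pairs.append((prev_c, i))
        prev_c = i if base == "C" else None
    return pairs


def kimura_cpg_divergence(pair: AlignedPair, cpg_correction: bool = True) -> float:
    """CpG-adjusted Kimura 2-parameter divergence (percent) of copy vs consensus.

    K = -1/2 * ln((1 - 2p - q) * sqrt(1 - 2q)) with p, q the transition and
    transversion proportions over comparable sites (both bases in {A,C,G,T}).
    With ``cpg_correction`` a transition at a consensus CpG position counts
    1/10, and transitions at both positions of one CpG count as a single
    (full) transition. Transversions are never down-weighted.
    """
    cons, copy = pair.consensus_seq, pair.copy_seq
    comparable = [
        i for i in range(len(cons)) if cons[i] in "ACGT" and copy[i] in "ACGT"
    ]
    if not comparable:
        raise ValueError("no comparable (ungapped, unambiguous) sites")
    comparable_set = set(comparable)

    cpg_cols: set[int] = set()
    cpg_pairs: list[tuple[int, int]] = []
    if cpg_correction:
        cpg_pairs = _consensus_cpg_pairs(cons)
        cpg_cols = {i for ij in cpg_pairs for i in ij}

    transitions = 0.0
    transversions = 0
    for i in comparable:
        a, b = cons[i], copy[i]
        if a == b:
            continue
        if (a, b) in TRANSITIONS:
            if i not in cpg_cols:
                transitions += 1.0
        else:
            transversions += 1

    for i, j in cpg_pairs:
        ti = i in comparable_set and copy[i] != cons[i] and (cons[i], copy[i]) in TRANSITIONS
        tj = j in comparable_set and copy[j] != cons[j] and (cons[j], copy[j]) in TRANSITIONS
        if ti and tj:
            transitions += 1.0
        elif ti or tj:
            transitions += 0.1

    n = len(comparable)
    p = transitions / n
    q = transversions / n
    arg1 = 1.0 - 2.0 * p - q
    arg2 = 1.0 - 2.0 * q
    if arg1 <= 0 or arg2 <= 0:
        raise SaturationError(f"divergence saturated (p={p:.4f}, q={q:.4f})")
    return -50.0 * math.log(arg1 * math.sqrt(arg2))


# ---------------------------------------------------------------------------
# Occupancy and profiles
# ---------------------------------------------------------------------------


def occupancy_by_class(
    annotations: Sequence[TEAnnotation], layout: GenomeLayout
) -> dict[str, tuple[int, float]]:
    """Per-class (union bp, percent of genome). Expects overlap-resolved input."""
    total = layout.total_bp
    return {
        cls: (bp, 100.0 * bp / total)
        for cls, bp in sorted(class_occupancy_bp(annotations).items())
    }


@dataclass
class DivergenceProfile:
    """Per-bin occupancy (bp) by group, over half-open divergence bins."""

    bin_edges: np.ndarray  # len n_bins + 1; final bin is the overflow bin
    occupancy_bp: dict[str, np.ndarray]
    genome_size: int

    def percent(self) -> dict[str, np.ndarray]:
        return {k: 100.0 * v / self.genome_size for k, v in self.occupancy_bp.items()}


def divergence_profile(
    annotations: Sequence[TEAnnotation],
    layout: GenomeLayout,
    bin_width: float = 1.0,
    max_divergence: float = 60.0,
    by: str = "te_class",
) -> DivergenceProfile:
    """Bin each element's length by its divergence into [lo, lo + width) bins.

    Elements beyond ``max_divergence`` fall into a single overflow bin, so
    the profile conserves total per-group occupancy exactly (length is used
    directly; overlap resolution is assumed done upstream).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(math.ceil(max_divergence / bin_width))
    edges = np.append(np.arange(n_bins + 1) * bin_width, np.inf)
    occupancy: dict[str, np.ndarray] = {}
    for a in annotations:
        key = getattr(a, by)
        arr = occupancy.setdefault(key, np.zeros(n_bins + 1, dtype=np.int64))
        b = min(int(a.divergence_pct // bin_width), n_bins)
        arr[b] += a.length
    return DivergenceProfile(bin_edges=edges, occupancy_bp=occupancy, genome_size=layout.total_bp)


# ---------------------------------------------------------------------------
# Composition tests
# ---------------------------------------------------------------------------


def plot_profile(profile: DivergenceProfile, path, title: str = "TE landscape"):
    """Stacked-bar landscape plot (percent of genome per divergence bin)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pct = profile.percent()
    edges = profile.bin_edges[:-2]  # drop the overflow bin from the plot
    fig, ax = plt.subplots(figsize=(8, 4))
    bottom = np.zeros(len(edges))
    width = float(edges[1] - edges[0]) if len(edges) > 1 else 1.0
    for cls in sorted(pct):
        vals = pct[cls][: len(edges)]
        ax.bar(edges, vals, width=width, bottom=bottom, align="edge", label=cls)
        bottom = bottom + vals
    ax.set_xlabel("divergence from consensus (%)")
    ax.set_ylabel("percent of genome")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def young_te_enrichment(
    annotations: Sequence[TEAnnotation],
    young_threshold: float = 1.0,
    focal_class: str = "LTR",
    units: str = "elements",
) -> EnrichmentResult:
    """Is the focal class overrepresented among the youngest TEs?

    Two-sided Fisher's exact test on the 2x2 table (focal vs other class) x
    (divergence < threshold vs not). ``units`` counts elements (default) or bp.
    """
    def w(a: TEAnnotation) -> int:
        return 1 if units == "elements" else a.length

    fy = fo = oy = oo = 0
    for a in annotations:
        young = a.divergence_pct < young_threshold
        if a.te_class == focal_class:
            fy, fo = fy + (w(a) if young else 0), fo + (0 if young else w(a))
        else:
            oy, oo = oy + (w(a) if young else 0), oo + (0 if young else w(a))
    if fy + fo == 0:
        raise ValueError(f"no elements of focal class {focal_class!r}")
    p = fisher_exact_two_sided([[fy, fo], [oy, oo]])
    total_young = fy + oy
    total = fy + fo + oy + oo
    expected = (fy + fo) * total_young / total if total else float("nan")
    return EnrichmentResult(
        unit=focal_class,
        observed=fy,
        expected_mean=expected,
        ratio=fy / expected if expected > 0 else float("nan"),
        p=p,
        q=p,
        test="fisher",
        extra={"table": [[fy, fo], [oy, oo]], "young_threshold": young_threshold},
    )


@dataclass
class AncientLineResult:
    """Ancient vs lineage-specific LINE composition in two annotation sets."""

    counts_a: tuple[int, int]  # (ancient, other) element counts
    counts_b: tuple[int, int]
    prop_bp_a: float  # ancient LINE bp / total LINE bp
    prop_bp_b: float
    p: float


def ancient_line_comparison(
    annotations_a: Sequence[TEAnnotation],
    annotations_b: Sequence[TEAnnotation],
    ancient_labels: set[str],
) -> AncientLineResult:
    """Compare the ancient share of LINE content between two genomes.

    ``ancient_labels`` names subfamilies shared since the species' common
    ancestor; everything else counts as lineage-specific/other. Proportions
    are reported in bp; the Fisher test uses element counts.
    """
    def split(annotations):
        anc_n = oth_n = anc_bp = oth_bp = 0
        for a in annotations:
            if a.te_class != "LINE":
                continue
            if a.subfamily in ancient_labels:
                anc_n += 1
                anc_bp += a.length
            else:
                oth_n += 1
                oth_bp += a.length
        return (anc_n, oth_n), (anc_bp, oth_bp)

    (na, oa), (ba, bo_a) = split(annotations_a)
    (nb, ob), (bb, bo_b) = split(annotations_b)
    prop_a = ba / (ba + bo_a) if ba + bo_a else float("nan")
    prop_b = bb / (bb + bo_b) if bb + bo_b else float("nan")
    if not ancient_labels:
        warnings.warn("empty ancient label set: proportions are 0, test skipped")
        return AncientLineResult((na, oa), (nb, ob), 0.0, 0.0, float("nan"))
    p = fisher_exact_two_sided([[na, oa], [nb, ob]])
    return AncientLineResult((na, oa), (nb, ob), prop_a, prop_b, p)
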