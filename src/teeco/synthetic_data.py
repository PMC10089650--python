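"""Synthetic genomes with planted TE structure and a ground-truth manifest.

The generator emulates the statistical structure the analysis modules
assume — per-subfamily divergence distributions, ERV hotspots (formed either
by independent insertion or by segmental duplication of one insertion),
ERV-interrupted LINEs whose fragments conjoin exactly in consensus
coordinates, strand-aware upstream insertion bias, and KZNF gene clusters
colocated with hotspots — so every pipeline stage can be tested against
known truth without any external download.

Placement is uniform per chromosome. By default copies are rejection-sampled
to be overlap-free (the detectors consume overlap-resolved annotations);
with ``allow_te_overlap`` placement is unconditional uniform, which makes
the generating process identical to the permutation null the enrichment
tests use — calibration datasets should set it.
"""

from __future__ import annotations

import dataclasses
import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    GeneAnnotation,
    GenomeLayout,
    TEAnnotation,
    write_bed_intervals,
    write_genes_gff3,
    write_layout,
    write_te_out,
)
from .intervals import merge
from .stats import rng_for


class PlacementError(RuntimeError):
    """Rejection sampling could not fit an interval (genome too crowded)."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubfamilySpec:
    name: str
    te_class: str  # {LINE, SINE, LTR, DNA, other}
    superfamily: str
    consensus_length: int
    n_copies: int
    divergence_mean: float
    divergence_sd: float
    lineage_specific: bool = True
    frac_full_length: float = 0.0
    length_frac_range: tuple[float, float] = (0.3, 1.0)


@dataclass(frozen=True)
class HotspotSpec:
    count: int
    width_bp: int = 100_000
    density_multiplier: float = 8.0
    mode: str = "independent-insertion"  # or "segmental-duplication"
    fill_subfamily: str = ""


@dataclass(frozen=True)
class NestingSpec:
    n_interruptions: int
    host_subfamily: str
    erv_subfamilies: tuple[str, ...]
    n_fragments: int = 2
    split_margin_bp: int = 500


@dataclass(frozen=True)
class KZNFSpec:
    n_clusters: int = 4
    genes_per_cluster: int = 10  # must be even (genes are paired as duplicates)
    colocate_with_hotspots: bool = True
    div_mean_in: float = 12.0  # nearest-duplicate divergence, hotspot clusters
    div_mean_out: float = 17.0
    div_sd: float = 3.0
    gene_length: int = 3000
    spacing_bp: int = 2000


@dataclass(frozen=True)
class GeneSpec:
    n_genes: int = 150
    frac_coding: float = 0.6
    frac_lncRNA: float = 0.2
    length_range: tuple[int, int] = (2000, 10_000)
    avoid_hotspots: bool = True  # ordinary genes are depleted from hotspot windows
    kznf: KZNFSpec | None = None


@dataclass(frozen=True)
class UpstreamBiasSpec:
    subfamily: str
    excess_factor: float
    window_bp: int = 5000


@dataclass(frozen=True)
class SDSpec:
    n_intervals: int = 10
    length_bp: int = 20_000


@dataclass(frozen=True)
class SimConfig:
    chromosome_lengths: tuple[int, ...]
    subfamilies: tuple[SubfamilySpec, ...]
    hotspots: HotspotSpec | None = None
    nesting: NestingSpec | None = None
    genes: GeneSpec | None = None
    upstream_bias: UpstreamBiasSpec | None = None
    sd: SDSpec | None = None
    seed: int = 0
    allow_te_overlap: bool = False

    def __post_init__(self):
        if any(l <= 0 for l in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        names = [s.name for s in self.subfamilies]
        if len(set(names)) != len(names):
            raise ValueError("duplicate subfamily names")
        if self.nesting is not None:
            host = self._subfamily(self.nesting.host_subfamily)
            if host.consensus_length <= 5000:
                raise ValueError("nesting host consensus must exceed 5,000 bp")
            for e in self.nesting.erv_subfamilies:
                if self._subfamily(e).te_class != "LTR":
                    raise ValueError(f"interrupting subfamily {e} must be LTR class")
        if self.hotspots is not None and self.hotspots.count > 0:
            fill = self._subfamily(self.hotspots.fill_subfamily)
            if fill.te_class != "LTR":
                raise ValueError("hotspot fill subfamily must be LTR class")
        if self.genes is not None and self.genes.kznf is not None:
            if self.genes.kznf.genes_per_cluster % 2:
                raise ValueError("genes_per_cluster must be even")
        if self.upstream_bias is not None:
            self._subfamily(self.upstream_bias.subfamily)

    def _subfamily(self, name: str) -> SubfamilySpec:
        for s in self.subfamilies:
            if s.name == name:
                return s
        raise ValueError(f"unknown subfamily {name!r}")


@dataclass
class SyntheticTruth:
    """Manifest of every planted event in a generated dataset."""

    seed: int
    interruptions: list[dict] = field(default_factory=list)
    hotspot_windows: list[tuple[str, int, int]] = field(default_factory=list)
    upstream_excess: dict = field(default_factory=dict)
    kznf: dict = field(default_factory=dict)
    sd_intervals: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    layout: GenomeLayout
    annotations: list[TEAnnotation]
    genes: list[GeneAnnotation]
    sd_intervals: list[tuple[str, int, int]]
    kznf_divergence: "object | None"  # pandas DataFrame when KZNFs were planted
    truth: SyntheticTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# Placement engine
# ---------------------------------------------------------------------------


class _Occupancy:
    """Per-chromosome occupied intervals with overlap rejection."""

    def __init__(self, layout: GenomeLayout, enabled: bool):
        self.enabled = enabled
        self.by_chrom: dict[str, list[tuple[int, int]]] = {n: [] for n, _ in layout.chromosomes}
        self.lengths = layout.lengths

    def _free(self, chrom: str, start: int, end: int) -> bool:
        ivs = self.by_chrom[chrom]
        i = bisect_left(ivs, (start, start))
        if i < len(ivs) and ivs[i][0] < end:
            return False
        if i > 0 and ivs[i - 1][1] > start:
            return False
        return True

    def place(
        self,
        rng: np.random.Generator,
        chrom: str,
        length: int,
        lo: int | None = None,
        hi: int | None = None,
        max_tries: int = 500,
    ) -> int:
        """Uniform start in [lo, hi - length]; rejection-sample if enabled."""
        lo = 0 if lo is None else lo
        hi = self.lengths[chrom] if hi is None else hi
        if hi - lo < length:
            raise PlacementError(f"interval of {length} bp cannot fit in {chrom}:{lo}-{hi}")
        for _ in range(max_tries):
            start = int(rng.integers(lo, hi - length + 1))
            if not self.enabled or self._free(chrom, start, start + length):
                if self.enabled:
                    insort(self.by_chrom[chrom], (start, start + length))
                return start
        raise PlacementError(
            f"could not place {length} bp on {chrom} after {max_tries} tries; "
            "reduce copy counts or chromosome occupancy"
        )


def _pick_chrom(rng: np.random.Generator, layout: GenomeLayout, min_len: int = 0) -> str:
    names = [n for n, l in layout.chromosomes if l >= min_len]
    if not names:
        raise PlacementError(f"no chromosome of length >= {min_len}")
    weights = np.array([layout.lengths[n] for n in names], dtype=float)
    return names[int(rng.choice(len(names), p=weights / weights.sum()))]


def _div(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(abs(rng.normal(mean, sd)))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate(config: SimConfig, outdir: str | Path | None = None) -> SyntheticDataset:
    """Build a synthetic dataset (and optionally write it to ``outdir``).

    Outputs: TE annotations (RepeatMasker-style ``.out``), genes (GFF3), SD
    intervals (BED), genome layout (TSV), KZNF pairwise divergence matrix
    (TSV) and the truth manifest (JSON). The same seed yields byte-identical
    files.
    """
    rng = rng_for(config.seed, "sim")
    names = tuple(f"chr{i + 1}" for i in range(len(config.chromosome_lengths)))
    layout = GenomeLayout(chromosomes=tuple(zip(names, config.chromosome_lengths)))
    occ = _Occupancy(layout, enabled=not config.allow_te_overlap)
    truth = SyntheticTruth(seed=config.seed)
    annotations: list[TEAnnotation] = []

    hotspot_windows = _plant_hotspot_windows(config, layout, rng, truth)
    _plant_interruptions(config, layout, occ, rng, truth, annotations)
    _fill_hotspots(config, layout, occ, rng, annotations, hotspot_windows)
    genes, kznf_matrix = _plant_genes(config, layout, rng, truth, hotspot_windows)
    _plant_upstream_bias(config, layout, occ, rng, truth, annotations, genes)
    _plant_background(config, layout, occ, rng, annotations)
    sd_intervals = _plant_sd(config, layout, rng, truth)

    annotations.sort(key=lambda a: (a.chrom, a.start, a.end))
    for i, a in enumerate(annotations):
        a.element_id = i
    # truth interruption records hold object references; materialise ids now
    for rec in truth.interruptions:
        rec["line_fragment_ids"] = [a.element_id for a in rec.pop("_fragments")]
        rec["erv_ids"] = [a.element_id for a in rec.pop("_ervs")]

    dataset = SyntheticDataset(
        layout=layout,
        annotations=annotations,
        genes=genes,
        sd_intervals=sd_intervals,
        kznf_divergence=kznf_matrix,
        truth=truth,
        config=config,
    )
    if outdir is not None:
        _write(dataset, Path(outdir))
    return dataset


def _plant_hotspot_windows(config, layout, rng, truth) -> list[tuple[str, int, int]]:
    if config.hotspots is None or config.hotspots.count == 0:
        return []
    hs = config.hotspots
    chosen: set[tuple[str, int]] = set()
    for _ in range(hs.count):
        for _try in range(200):
            chrom = _pick_chrom(rng, layout, min_len=hs.width_bp)
            n_windows = layout.lengths[chrom] // hs.width_bp
            w = int(rng.integers(0, n_windows))
            if (chrom, w) not in chosen:
                chosen.add((chrom, w))
                break
        else:
            raise PlacementError("could not choose distinct hotspot windows")
    windows = sorted(
        (chrom, w * hs.width_bp, (w + 1) * hs.width_bp) for chrom, w in chosen
    )
    truth.hotspot_windows = windows
    return windows


def _split_consensus(rng, cl: int, n_fragments: int, margin: int) -> list[tuple[int, int]]:
    """Split [1, cl] into n_fragments contiguous 1-based consensus chunks."""
    cuts = sorted(
        int(rng.integers(margin, cl - margin + 1)) for _ in range(n_fragments - 1)
    )
    # enforce distinct cut points with some room
    for i in range(1, len(cuts)):
        cuts[i] = max(cuts[i], cuts[i - 1] + margin)
    bounds = [0, *cuts, cl]
    return [(bounds[i] + 1, bounds[i + 1]) for i in range(n_fragments)]


def _plant_interruptions(config, layout, occ, rng, truth, annotations) -> None:
    if config.nesting is None or config.nesting.n_interruptions == 0:
        return
    ns = config.nesting
    host = config._subfamily(ns.host_subfamily)
    cl = host.consensus_length
    for idx in range(ns.n_interruptions):
        erv_spec = config._subfamily(ns.erv_subfamilies[idx % len(ns.erv_subfamilies)])
        erv_len = erv_spec.consensus_length
        chunks = _split_consensus(rng, cl, ns.n_fragments, ns.split_margin_bp)
        total_len = cl + erv_len * (ns.n_fragments - 1)
        chrom = _pick_chrom(rng, layout, min_len=total_len + 1)
        start = occ.place(rng, chrom, total_len)
        strand = "+" if rng.random() < 0.5 else "-"
        host_div = _div(rng, host.divergence_mean, host.divergence_sd)

        genomic_chunks = chunks if strand == "+" else chunks[::-1]
        frags: list[TEAnnotation] = []
        ervs: list[TEAnnotation] = []
        pos = start
        for j, (cs, ce) in enumerate(genomic_chunks):
            frag = TEAnnotation(
                element_id=-1, chrom=chrom, start=pos, end=pos + (ce - cs + 1),
                strand=strand, subfamily=host.name, te_class=host.te_class,
                superfamily=host.superfamily, lineage_specific=host.lineage_specific,
                divergence_pct=host_div, cons_start=cs, cons_end=ce,
                cons_remaining=cl - ce,
            )
            frags.append(frag)
            pos = frag.end
            if j < len(genomic_chunks) - 1:
                erv = TEAnnotation(
                    element_id=-1, chrom=chrom, start=pos, end=pos + erv_len,
                    strand="+" if rng.random() < 0.5 else "-",
                    subfamily=erv_spec.name, te_class="LTR",
                    superfamily=erv_spec.superfamily,
                    lineage_specific=erv_spec.lineage_specific,
                    divergence_pct=_div(rng, erv_spec.divergence_mean, erv_spec.divergence_sd),
                    cons_start=1, cons_end=erv_len, cons_remaining=0,
                )
                ervs.append(erv)
                pos = erv.end
        annotations.extend(frags)
        annotations.extend(ervs)
        truth.interruptions.append(
            {
                "chrom": chrom,
                "span": (start, start + total_len),
                "strand": strand,
                "line_subfamily": host.name,
                "erv_subfamilies": [e.subfamily for e in ervs],
                "n_fragments": ns.n_fragments,
                "conjoined_cons_len": cl,
                "_fragments": frags,
                "_ervs": ervs,
            }
        )


def _mean_copy_len(s: SubfamilySpec) -> float:
    lo, hi = s.length_frac_range
    mean_frac = (lo + hi) / 2
    return s.frac_full_length * s.consensus_length + (1 - s.frac_full_length) * mean_frac * s.consensus_length


def _fill_hotspots(config, layout, occ, rng, annotations, hotspot_windows) -> None:
    if not hotspot_windows:
        return
    hs = config.hotspots
    fill = config._subfamily(hs.fill_subfamily)
    erv_bp = sum(_mean_copy_len(s) * s.n_copies for s in config.subfamilies if s.te_class == "LTR")
    base_density = erv_bp / layout.total_bp
    target_density = min(0.8, hs.density_multiplier * base_density)
    for chrom, ws, we in hotspot_windows:
        target_bp = int(target_density * (we - ws))
        sd_div = _div(rng, fill.divergence_mean, fill.divergence_sd)
        placed = 0
        while placed < target_bp:
            length = max(100, int(fill.consensus_length * rng.uniform(*fill.length_frac_range)))
            if hs.mode == "segmental-duplication":
                div = float(abs(sd_div + rng.normal(0, 0.05)))
            else:
                div = _div(rng, fill.divergence_mean, fill.divergence_sd)
            try:
                start = occ.place(rng, chrom, length, lo=ws, hi=we)
            except PlacementError:
                break  # window saturated; density target approached from below
            cs = int(rng.integers(1, fill.consensus_length - length + 2))
            annotations.append(
                TEAnnotation(
                    element_id=-1, chrom=chrom, start=start, end=start + length,
                    strand="+" if rng.random() < 0.5 else "-",
                    subfamily=fill.name, te_class="LTR", superfamily=fill.superfamily,
                    lineage_specific=fill.lineage_specific, divergence_pct=div,
                    cons_start=cs, cons_end=cs + length - 1,
                    cons_remaining=fill.consensus_length - (cs + length - 1),
                )
            )
            placed += length


def _plant_genes(config, layout, rng, truth, hotspot_windows):
    if config.genes is None:
        return [], None
    import pandas as pd

    gs = config.genes
    gene_occ = _Occupancy(layout, enabled=True)
    genes: list[GeneAnnotation] = []

    hot_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, ws, we in hotspot_windows:
        hot_by_chrom.setdefault(chrom, []).append((ws, we))

    def in_hotspot_window(chrom: str, s: int, e: int) -> bool:
        return any(s < he and e > hs_ for hs_, he in hot_by_chrom.get(chrom, []))

    kznf_ids_in: list[str] = []
    kznf_ids_out: list[str] = []
    pair_divs: dict[tuple[str, str], float] = {}
    if gs.kznf is not None:
        kz = gs.kznf
        cluster_len = kz.genes_per_cluster * (kz.gene_length + kz.spacing_bp)
        for c in range(kz.n_clusters):
            # alternate clusters in/out of hotspots so both age groups exist
            in_hotspot = kz.colocate_with_hotspots and bool(hotspot_windows) and c % 2 == 0
            if in_hotspot:
                chrom, ws, we = hotspot_windows[(c // 2) % len(hotspot_windows)]
                lo, hi = ws, we
                if hi - lo < cluster_len:
                    hi = min(layout.lengths[chrom], lo + cluster_len + kz.spacing_bp)
                anchor = gene_occ.place(rng, chrom, cluster_len, lo=lo, hi=hi)
            else:
                # non-colocated clusters stay clear of hotspot windows
                for _try in range(200):
                    chrom = _pick_chrom(rng, layout, min_len=cluster_len + 1)
                    anchor = gene_occ.place(rng, chrom, cluster_len)
                    if not in_hotspot_window(chrom, anchor, anchor + cluster_len):
                        break
                    gene_occ.by_chrom[chrom].remove((anchor, anchor + cluster_len))
                else:
                    raise PlacementError("could not place KZNF cluster outside hotspots")
            mean = kz.div_mean_in if in_hotspot else kz.div_mean_out
            pos = anchor
            cluster_ids = []
            for g in range(kz.genes_per_cluster):
                gid = f"KZNF_c{c}_{g}"
                strand = "+" if rng.random() < 0.5 else "-"
                s, e = pos, pos + kz.gene_length
                genes.append(
                    GeneAnnotation(
                        gene_id=gid, chrom=chrom, start=s, end=e, strand=strand,
                        biotype="coding",
                        cds_intervals=((s + 200, e - 200),),
                        is_kznf=True, is_lineage_specific=True,
                    )
                )
                cluster_ids.append(gid)
                (kznf_ids_in if in_hotspot else kznf_ids_out).append(gid)
                pos = e + kz.spacing_bp
            for a, b in zip(cluster_ids[::2], cluster_ids[1::2]):
                d = max(0.5, float(rng.normal(mean, kz.div_sd)))
                pair_divs[(a, b)] = d

    for i in range(gs.n_genes):
        length = int(rng.integers(gs.length_range[0], gs.length_range[1] + 1))
        start = None
        for _try in range(100):
            chrom = _pick_chrom(rng, layout, min_len=length + 1)
            try:
                cand = gene_occ.place(rng, chrom, length)
            except PlacementError:
                continue
            if gs.avoid_hotspots and in_hotspot_window(chrom, cand, cand + length):
                # undo the tentative placement and retry elsewhere
                gene_occ.by_chrom[chrom].remove((cand, cand + length))
                continue
            start = cand
            break
        if start is None:
            continue
        u = rng.random()
        biotype = "coding" if u < gs.frac_coding else ("lncRNA" if u < gs.frac_coding + gs.frac_lncRNA else "other")
        cds: tuple[tuple[int, int], ...] = ()
        if biotype == "coding" and length > 800:
            cds = ((start + 200, start + 200 + min(600, length - 400)),)
        genes.append(
            GeneAnnotation(
                gene_id=f"gene_{i}", chrom=chrom, start=start, end=start + length,
                strand="+" if rng.random() < 0.5 else "-", biotype=biotype,
                cds_intervals=cds,
            )
        )

    matrix = None
    if gs.kznf is not None:
        ids = sorted(kznf_ids_in + kznf_ids_out)
        n = len(ids)
        far = 40.0 + np.abs(rng.normal(0, 3.0, size=(n, n)))
        vals = np.triu(far, k=1)
        vals = vals + vals.T
        matrix = pd.DataFrame(vals, index=ids, columns=ids)
        for (a, b), d in pair_divs.items():
            matrix.loc[a, b] = d
            matrix.loc[b, a] = d
        np.fill_diagonal(matrix.values, 0.0)
        truth.kznf = {
            "in_hotspot_ids": sorted(kznf_ids_in),
            "out_hotspot_ids": sorted(kznf_ids_out),
            "div_mean_in": gs.kznf.div_mean_in,
            "div_mean_out": gs.kznf.div_mean_out,
        }

    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes, matrix


def _plant_upstream_bias(config, layout, occ, rng, truth, annotations, genes) -> None:
    if config.upstream_bias is None:
        return
    ub = config.upstream_bias
    spec = config._subfamily(ub.subfamily)
    from .distribution import upstream_regions

    regions = upstream_regions(genes, layout, ub.window_bp)
    if not regions:
        raise ValueError("upstream bias requested but no genes were planted")
    mean_len = _mean_copy_len(spec)
    by_strand: dict[str, list[tuple[str, int, int]]] = {"+": [], "-": []}
    for chrom, strand, s, e, _ in regions:
        by_strand[strand].append((chrom, s, e))
    # expected uniform hit rate: an element overlaps a region iff its start
    # falls within (region expanded left by len-1), averaged over strands
    frac = {
        strand: sum(
            min(layout.lengths[c], e - s + mean_len - 1) for c, s, e in merged
        ) / layout.total_bp
        for strand, merged in (
            (st, [(c, s, e) for c, s, e in _merge_regions(by_strand[st])]) for st in "+-"
        )
    }
    base_rate = 0.5 * (frac["+"] + frac["-"])
    n_in = min(spec.n_copies, int(round(ub.excess_factor * base_rate * spec.n_copies)))

    placed = 0
    failures = 0
    flat = [(chrom, strand, s, e) for chrom, strand, s, e, _ in regions]
    while placed < n_in:
        chrom, strand, s, e = flat[int(rng.integers(0, len(flat)))]
        length = max(50, int(spec.consensus_length * rng.uniform(*spec.length_frac_range)))
        lo = max(0, s - length + 1)
        hi = min(layout.lengths[chrom], e + length - 1)
        try:
            start = occ.place(rng, chrom, length, lo=lo, hi=hi, max_tries=50)
        except PlacementError:
            failures += 1
            if failures > 20 * max(1, n_in):
                raise PlacementError("upstream regions too crowded for requested bias")
            continue
        annotations.append(_background_copy(rng, spec, chrom, start, length, strand=strand))
        placed += 1
    _place_copies(config, layout, occ, rng, annotations, spec, spec.n_copies - n_in)
    truth.upstream_excess[spec.name] = {
        "excess_factor": ub.excess_factor,
        "n_in_regions": n_in,
        "expected_uniform": base_rate * spec.n_copies,
    }


def _merge_regions(regions: list[tuple[str, int, int]]):
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in regions:
        by_chrom.setdefault(c, []).append((s, e))
    out = []
    for c, ivs in by_chrom.items():
        out.extend((c, s, e) for s, e in merge(ivs))
    return out


def _background_copy(rng, spec: SubfamilySpec, chrom: str, start: int, length: int, strand=None) -> TEAnnotation:
    cl = spec.consensus_length
    if length >= cl:
        length = cl
        cs, ce = 1, cl
    else:
        cs = int(rng.integers(1, cl - length + 2))
        ce = cs + length - 1
    return TEAnnotation(
        element_id=-1, chrom=chrom, start=start, end=start + length,
        strand=strand if strand is not None else ("+" if rng.random() < 0.5 else "-"),
        subfamily=spec.name, te_class=spec.te_class, superfamily=spec.superfamily,
        lineage_specific=spec.lineage_specific,
        divergence_pct=_div(rng, spec.divergence_mean, spec.divergence_sd),
        cons_start=cs, cons_end=ce, cons_remaining=cl - ce,
    )


def _place_copies(config, layout, occ, rng, annotations, spec: SubfamilySpec, n: int) -> None:
    for _ in range(n):
        if rng.random() < spec.frac_full_length:
            length = spec.consensus_length
        else:
            length = max(50, int(spec.consensus_length * rng.uniform(*spec.length_frac_range)))
        chrom = _pick_chrom(rng, layout, min_len=length + 1)
        start = occ.place(rng, chrom, length)
        annotations.append(_background_copy(rng, spec, chrom, start, length))


def _plant_background(config, layout, occ, rng, annotations) -> None:
    biased = config.upstream_bias.subfamily if config.upstream_bias else None
    for spec in config.subfamilies:
        if spec.name == biased:
            continue  # already placed with its bias
        _place_copies(config, layout, occ, rng, annotations, spec, spec.n_copies)


def _plant_sd(config, layout, rng, truth) -> list[tuple[str, int, int]]:
    if config.sd is None or config.sd.n_intervals == 0:
        return []
    out = []
    for _ in range(config.sd.n_intervals):
        chrom = _pick_chrom(rng, layout, min_len=config.sd.length_bp + 1)
        start = int(rng.integers(0, layout.lengths[chrom] - config.sd.length_bp + 1))
        out.append((chrom, start, start + config.sd.length_bp))
    out.sort()
    truth.sd_intervals = out
    return out


def _write(dataset: SyntheticDataset, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_te_out(dataset.annotations, outdir / "te_annotations.out")
    write_genes_gff3(dataset.genes, outdir / "genes.gff3")
    write_bed_intervals(dataset.sd_intervals, outdir / "sd_intervals.bed")
    write_layout(dataset.layout, outdir / "layout.tsv")
    if dataset.kznf_divergence is not None:
        dataset.kznf_divergence.to_csv(outdir / "kznf_divergence.tsv", sep="\t")
    manifest = dataclasses.asdict(dataset.truth)
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Bundled configurations
# ---------------------------------------------------------------------------


def null_config(base: SimConfig) -> SimConfig:
    """Strip all planted structure for calibration runs (idempotent).

    Removes interruptions, hotspot planting, upstream bias and the KZNF age
    shift; keeps chromosomes, subfamily table, gene layout and seed.
    """
    genes = base.genes
    if genes is not None and genes.kznf is not None:
        kz = replace(genes.kznf, colocate_with_hotspots=False, div_mean_in=genes.kznf.div_mean_out)
        genes = replace(genes, kznf=kz)
    return replace(base, nesting=None, hotspots=None, upstream_bias=None, genes=genes)


def planted_interruption_config(seed: int = 0, n_interruptions: int = 50) -> SimConfig:
    """10-Mb, 5-chromosome genome with ~5,000 TE annotations and planted
    ERV-in-LINE interruptions — the reference conditions for detector
    recovery checks. The matched control is ``null_config`` of this."""
    subfamilies = (
        SubfamilySpec("L1_Pm_host", "LINE", "L1", 6100, 800, 17.0, 5.0,
                      length_frac_range=(0.1, 0.5)),
        SubfamilySpec("L1_Pm_b", "LINE", "L1", 4000, 700, 22.0, 5.0,
                      length_frac_range=(0.1, 0.6)),
        SubfamilySpec("B1_Pm", "SINE", "B1", 150, 1500, 12.0, 6.0),
        SubfamilySpec("Pm_ERV2_a", "LTR", "ERVK", 1200, 500, 8.0, 4.0),
        SubfamilySpec("Pm_ERV2_b", "LTR", "ERVK", 900, 500, 10.0, 4.0),
        SubfamilySpec("Pm_MaLR", "LTR", "MaLR", 600, 500, 20.0, 6.0),
        SubfamilySpec("Tig_DNA", "DNA", "TcMar", 500, 500, 25.0, 7.0, lineage_specific=False),
    )
    return SimConfig(
        chromosome_lengths=(2_000_000,) * 5,
        subfamilies=subfamilies,
        nesting=NestingSpec(
            n_interruptions=n_interruptions,
            host_subfamily="L1_Pm_host",
            erv_subfamilies=("Pm_ERV2_a", "Pm_ERV2_b"),
        ),
        seed=seed,
    )


def calibration_config(seed: int = 0, n_erv_subfamilies: int = 20,
                       copies_per_subfamily: int = 750, n_genes: int = 250,
                       upstream_excess: float | None = None) -> SimConfig:
    """Null genome for permutation-calibration runs.

    No planted structure; TEs are placed with overlaps allowed so the
    data-generating process is exactly the per-chromosome uniform null the
    permutation tests randomize against. A dense LINE background provides
    many same-subfamily flanking pairs, and genes provide upstream regions,
    so the test statistics have wide (well-calibrated) null distributions.
    With ``upstream_excess`` the first ERV subfamily is planted into 5-kb
    same-strand upstream regions at that multiple of its uniform expectation
    (the positive control for the upstream enrichment test). A planted
    excess of E requires the uniform hit rate to stay below 1/E — pass a
    smaller ``n_genes`` (shrinking upstream coverage) for large E.
    """
    ervs = tuple(
        SubfamilySpec(f"Pm_ERV_cal{i}", "LTR", "ERVK", 250, copies_per_subfamily,
                      10.0, 4.0, length_frac_range=(0.6, 1.0))
        for i in range(n_erv_subfamilies)
    )
    subfamilies = (
        SubfamilySpec("L1_cal", "LINE", "L1", 5500, 600, 18.0, 5.0,
                      length_frac_range=(0.05, 0.1)),
        *ervs,
    )
    bias = (
        UpstreamBiasSpec(subfamily="Pm_ERV_cal0", excess_factor=upstream_excess)
        if upstream_excess is not None
        else None
    )
    return SimConfig(
        chromosome_lengths=(1_000_000,) * 3,
        subfamilies=subfamilies,
        genes=GeneSpec(n_genes=n_genes, length_range=(2000, 6000), kznf=None),
        upstream_bias=bias,
        seed=seed,
        allow_te_overlap=True,
    )


def sd_hotspot_config(seed: int = 0) -> SimConfig:
    """Hotspots formed by segmental duplication: within-hotspot ERV copies
    share one divergence value, so neighbor delta-divergences collapse to
    ~0 inside hotspots while staying wide outside."""
    subfamilies = (
        SubfamilySpec("Pm_ERV_bg", "LTR", "ERVK", 1000, 600, 15.0, 6.0,
                      length_frac_range=(0.4, 0.9)),
        SubfamilySpec("Pm_ERV_dup", "LTR", "ERVK", 1000, 0, 15.0, 6.0,
                      length_frac_range=(0.4, 0.9)),
        SubfamilySpec("L1_bg", "LINE", "L1", 6000, 300, 20.0, 5.0,
                      length_frac_range=(0.1, 0.4)),
    )
    return SimConfig(
        chromosome_lengths=(2_000_000,) * 5,
        subfamilies=subfamilies,
        hotspots=HotspotSpec(count=5, width_bp=100_000, density_multiplier=10.0,
                             mode="segmental-duplication", fill_subfamily="Pm_ERV_dup"),
        seed=seed,
    )


def kznf_shift_config(seed: int = 0) -> SimConfig:
    """KZNF clusters with a planted -5-point duplicate-age shift for
    hotspot-colocated clusters (50 genes per group)."""
    subfamilies = (
        SubfamilySpec("Pm_ERV_hs", "LTR", "ERVK", 800, 400, 16.0, 5.0),
        SubfamilySpec("L1_bg", "LINE", "L1", 6000, 200, 20.0, 5.0,
                      length_frac_range=(0.1, 0.4)),
    )
    return SimConfig(
        chromosome_lengths=(2_000_000,) * 5,
        subfamilies=subfamilies,
        hotspots=HotspotSpec(count=5, width_bp=100_000, density_multiplier=8.0,
                             fill_subfamily="Pm_ERV_hs"),
        genes=GeneSpec(
            n_genes=100,
            kznf=KZNFSpec(n_clusters=10, genes_per_cluster=10,
                          div_mean_in=12.0, div_mean_out=17.0, div_sd=3.0),
        ),
        seed=seed,
    )


def rodentlike_config(seed: int = 0) -> SimConfig:
    """A small bundled configuration with the qualitative structure the real
    data shows: an ERV-dominated young end of the divergence landscape,
    declining LINE gains on recent timescales, an abundant nonautonomous-style
    ERVK subfamily with many gap-free full-length copies, ERV hotspots, an
    upstream-biased ERV subfamily, and hotspot-colocated KZNF clusters."""
    subfamilies = (
        SubfamilySpec("L1_Pm_1", "LINE", "L1", 6100, 400, 18.0, 6.0),
        SubfamilySpec("L1_MM_anc", "LINE", "L1", 6000, 200, 28.0, 5.0, lineage_specific=False),
        SubfamilySpec("B1_Pm", "SINE", "B1", 150, 600, 10.0, 5.0),
        SubfamilySpec("Pm_ERVK_young", "LTR", "ERVK", 3000, 500, 2.0, 1.5, frac_full_length=0.05),
        SubfamilySpec("Pm_ERVK_na", "LTR", "ERVK", 5200, 60, 16.0, 4.0, frac_full_length=0.25),
        SubfamilySpec("MaLR_old", "LTR", "MaLR", 2500, 150, 30.0, 6.0, lineage_specific=False),
        SubfamilySpec("MT2_reg", "LTR", "ERVL", 500, 200, 15.0, 4.0),
        SubfamilySpec("hAT_anc", "DNA", "hAT", 1000, 100, 25.0, 8.0, lineage_specific=False),
    )
    return SimConfig(
        chromosome_lengths=(2_000_000,) * 5,
        subfamilies=subfamilies,
        hotspots=HotspotSpec(count=6, width_bp=100_000, density_multiplier=6.0,
                             fill_subfamily="Pm_ERVK_young"),
        nesting=NestingSpec(n_interruptions=25, host_subfamily="L1_Pm_1",
                            erv_subfamilies=("Pm_ERVK_young", "Pm_ERVK_na")),
        genes=GeneSpec(n_genes=400, kznf=KZNFSpec(n_clusters=4, genes_per_cluster=6,
                                                  gene_length=2000, spacing_bp=1000)),
        upstream_bias=UpstreamBiasSpec(subfamily="MT2_reg", excess_factor=8.0),
        sd=SDSpec(n_intervals=10, length_bp=20_000),
        seed=seed,
    )
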