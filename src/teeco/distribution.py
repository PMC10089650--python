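"""Genomic distribution of TEs: coverage, distances, enrichment, hotspots.

All permutation nulls share one randomizer: uniform per-chromosome
re-placement of the shuffled elements with lengths preserved and every other
annotation held fixed (overlaps with fixed annotations are permitted, as in
a genome-wide uniform null). p-values are (r+1)/(n_perm+1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalIndex, intersect_length, merge, total_length
from .io_formats import GeneAnnotation, GenomeLayout, TEAnnotation
from .stats import (
    EnrichmentResult,
    bonferroni,
    fisher_exact_two_sided,
    mann_whitney_u,
    permutation_pvalue,
    place_uniform,
    rng_for,
)


@dataclass
class HotspotWindow:
    chrom: str
    window: tuple[int, int]
    erv_density: float
    gene_density: float = float("nan")
    is_hotspot: bool = False

    @property
    def length(self) -> int:
        return self.window[1] - self.window[0]


# ---------------------------------------------------------------------------
# Feature coverage
# ---------------------------------------------------------------------------


def _te_intervals_by_chrom(
    annotations: Sequence[TEAnnotation], pred: Callable[[TEAnnotation], bool] = lambda a: True
) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for a in annotations:
        if pred(a):
            out.setdefault(a.chrom, []).append((a.start, a.end))
    return out


def _feature_sets(
    genes: Sequence[GeneAnnotation], layout: GenomeLayout
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    feats: dict[str, dict[str, list[tuple[int, int]]]] = {
        "CDS": {},
        "lncRNA": {},
        "gene_body": {},
    }
    for g in genes:
        feats["gene_body"].setdefault(g.chrom, []).append((g.start, g.end))
        if g.biotype == "lncRNA":
            feats["lncRNA"].setdefault(g.chrom, []).append((g.start, g.end))
        for s, e in g.cds_intervals:
            feats["CDS"].setdefault(g.chrom, []).append((s, e))
    for chrom, length in layout.chromosomes:
        feats[f"chrom:{chrom}"] = {chrom: [(0, length)]}
    return feats


def _coverage(te_iv: dict[str, list], feat_iv: dict[str, list]) -> tuple[int, int]:
    feat_bp = sum(total_length(v) for v in feat_iv.values())
    cov = sum(
        intersect_length(te_iv.get(chrom, []), ivs) for chrom, ivs in feat_iv.items()
    )
    return cov, feat_bp


def feature_te_coverage(
    annotations: Sequence[TEAnnotation],
    genes: Sequence[GeneAnnotation],
    layout: GenomeLayout,
    with_null: bool = False,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, dict[str, float]] | None]:
    """TE coverage (covered bp / feature bp) per feature class and TE class.

    With ``with_null`` the total-TE coverage of each feature class is also
    compared against uniform per-chromosome re-placement of all TEs:
    ``p_depleted`` = (#{null <= observed}+1)/(n_perm+1) and ``p_enriched``
    symmetric — the depletion p is the contract for CDS avoidance.
    """
    feats = _feature_sets(genes, layout)
    te_classes = sorted({a.te_class for a in annotations}) + ["all"]
    rows = []
    for feat_name, feat_iv in feats.items():
        for cls in te_classes:
            pred = (lambda a: True) if cls == "all" else (lambda a, c=cls: a.te_class == c)
            cov, feat_bp = _coverage(_te_intervals_by_chrom(annotations, pred), feat_iv)
            rows.append(
                {
                    "feature": feat_name,
                    "te_class": cls,
                    "covered_bp": cov,
                    "feature_bp": feat_bp,
                    "coverage": cov / feat_bp if feat_bp else float("nan"),
                }
            )
    table = pd.DataFrame(rows)

    pvals = None
    if with_null:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        lengths = layout.lengths
        observed = {
            name: _coverage(_te_intervals_by_chrom(annotations), iv)[0]
            for name, iv in feats.items()
        }
        null_cov = {name: np.zeros(n_perm) for name in feats}
        by_chrom: dict[str, list[int]] = {}
        for a in annotations:
            by_chrom.setdefault(a.chrom, []).append(a.length)
        rng = rng_for(seed, "feature_coverage")
        starts_by_chrom = {
            chrom: place_uniform(rng, np.array(lens), lengths[chrom], n_perm)
            for chrom, lens in sorted(by_chrom.items())
        }
        for k in range(n_perm):
            te_iv = {
                chrom: [
                    (int(s), int(s) + l)
                    for s, l in zip(starts_by_chrom[chrom][k], by_chrom[chrom])
                ]
                for chrom in by_chrom
            }
            for name, iv in feats.items():
                null_cov[name][k] = _coverage(te_iv, iv)[0]
        pvals = {}
        for name in feats:
            null = null_cov[name]
            obs = observed[name]
            pvals[name] = {
                "p_depleted": (float(np.sum(null <= obs)) + 1) / (n_perm + 1),
                "p_enriched": (float(np.sum(null >= obs)) + 1) / (n_perm + 1),
            }
    return table, pvals


# ---------------------------------------------------------------------------
# Nearest-gene distances
# ---------------------------------------------------------------------------


def nearest_gene_distances(
    annotations: Sequence[TEAnnotation],
    genes: Sequence[GeneAnnotation],
    mode: str = "unstranded",
) -> pd.DataFrame:
    """Distance (gap bp; 0 when overlapping) from each element to its nearest gene.

    ``stranded`` restricts candidate genes to the element's own strand; when
    no candidate exists on the chromosome the distance is missing (NaN).
    """
    if mode not in ("stranded", "unstranded"):
        raise ValueError(f"unknown mode {mode!r}")
    gene_pos: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    keys = (
        {(g.chrom, g.strand) for g in genes}
        if mode == "stranded"
        else {(g.chrom, ".") for g in genes}
    )
    for chrom, strand in keys:
        sel = [
            g for g in genes if g.chrom == chrom and (mode == "unstranded" or g.strand == strand)
        ]
        starts = np.array(sorted(g.start for g in sel), dtype=np.int64)
        # for the "previous gene" lookup we need ends sorted independently
        ends = np.array(sorted(g.end for g in sel), dtype=np.int64)
        gene_pos[(chrom, strand)] = (starts, ends)

    rows = []
    for a in annotations:
        key = (a.chrom, a.strand if mode == "stranded" else ".")
        if key not in gene_pos:
            dist = float("nan")
        else:
            starts, ends = gene_pos[key]
            # nearest gene to the right: smallest start >= a.end
            i = int(np.searchsorted(starts, a.end, side="left"))
            right = starts[i] - a.end if i < len(starts) else None
            # nearest gene to the left: largest end <= a.start
            j = int(np.searchsorted(ends, a.start, side="right")) - 1
            left = a.start - ends[j] if j >= 0 else None
            candidates = [d for d in (right, left) if d is not None]
            dist = float(min(candidates)) if candidates else float("nan")
            if _overlaps_any(a, gene_pos, key):
                dist = 0.0
        rows.append({"element_id": a.element_id, "subfamily": a.subfamily, "distance": dist})
    return pd.DataFrame(rows)


def _overlaps_any(a: TEAnnotation, gene_pos, key) -> bool:
    starts, ends = gene_pos[key]
    if not len(starts):
        return False
    # genes sorted by start; candidate genes start before a.end
    i = int(np.searchsorted(starts, a.end, side="left"))
    if i == 0:
        return False
    # among genes starting before a.end, is there one ending after a.start?
    # ends array is sorted globally; the max end among the first i genes is
    # >= the i-th largest... use a cheap sufficient check on sorted ends:
    n_end_le = int(np.searchsorted(ends, a.start, side="right"))
    # genes fully left of the element have end <= a.start; if fewer such
    # genes than genes starting before a.end, some gene overlaps it.
    return n_end_le < i


def compare_distance_modes(
    annotations: Sequence[TEAnnotation], genes: Sequence[GeneAnnotation]
) -> dict:
    """Two-sided Mann-Whitney U between stranded and unstranded nearest-gene
    distances (elements with undefined stranded distance are dropped)."""
    d_s = nearest_gene_distances(annotations, genes, mode="stranded")["distance"].dropna()
    d_u = nearest_gene_distances(annotations, genes, mode="unstranded")["distance"].dropna()
    u, p = mann_whitney_u(d_s.to_numpy(), d_u.to_numpy())
    return {
        "U": u,
        "p": p,
        "median_stranded": float(d_s.median()),
        "median_unstranded": float(d_u.median()),
        "n_stranded": int(d_s.size),
        "n_unstranded": int(d_u.size),
    }


# ---------------------------------------------------------------------------
# Upstream enrichment and the SD confound
# ---------------------------------------------------------------------------


def upstream_regions(
    genes: Sequence[GeneAnnotation], layout: GenomeLayout, window_bp: int = 5000
) -> list[tuple[str, str, int, int, str]]:
    """Per-gene 5' upstream windows: (chrom, strand, start, end, gene_id).

    For a + gene the window is [start - w, start); for a - gene it is
    [end, end + w); both clipped to the chromosome. Regions of different
    genes are deliberately not merged (per-gene counting downstream).
    """
    lengths = layout.lengths
    out = []
    for g in genes:
        if g.strand == "+":
            s, e = max(0, g.start - window_bp), g.start
        else:
            s, e = g.end, min(lengths[g.chrom], g.end + window_bp)
        if e > s:
            out.append((g.chrom, g.strand, s, e, g.gene_id))
    return out


def _region_index(
    regions: Sequence[tuple[str, str, int, int, str]]
) -> dict[tuple[str, str], IntervalIndex]:
    grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for chrom, strand, s, e, _ in regions:
        grouped.setdefault((chrom, strand), []).append((s, e))
    return {k: IntervalIndex(merge(v), merged=True) for k, v in grouped.items()}


def upstream_enrichment(
    annotations: Sequence[TEAnnotation],
    genes: Sequence[GeneAnnotation],
    layout: GenomeLayout,
    window_bp: int = 5000,
    n_perm: int = 1000,
    seed: int = 0,
    subfamilies: Sequence[str] | None = None,
) -> list[EnrichmentResult]:
    """Per-subfamily enrichment within 5-kb upstream regions of same-strand genes.

    Observed: elements of the subfamily intersecting an upstream window of a
    gene on the element's strand. Expected: mean of the same count over
    ``n_perm`` uniform per-chromosome re-placements. p is a two-sided Fisher
    test comparing observed vs (rounded) expected counts in/out of regions;
    the permutation p is reported alongside (``p_perm``); q = Bonferroni
    over subfamilies on the Fisher p.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    regions = upstream_regions(genes, layout, window_bp)
    ridx = _region_index(regions)
    lengths = layout.lengths
    if subfamilies is None:
        subfamilies = sorted({a.subfamily for a in annotations if a.is_erv})

    results = []
    for sub in sorted(subfamilies):
        focal = [a for a in annotations if a.subfamily == sub]
        if not focal:
            continue
        observed = sum(
            1
            for a in focal
            if (a.chrom, a.strand) in ridx
            and bool(ridx[(a.chrom, a.strand)].overlaps(a.start, a.end))
        )
        rng = rng_for(seed, "upstream", sub)
        null = np.zeros(n_perm, dtype=np.int64)
        by_chrom: dict[str, list[TEAnnotation]] = {}
        for a in focal:
            by_chrom.setdefault(a.chrom, []).append(a)
        for chrom, anns in sorted(by_chrom.items()):
            lens = np.array([a.length for a in anns], dtype=np.int64)
            starts = place_uniform(rng, lens, lengths[chrom], n_perm)
            hit = np.zeros(starts.shape, dtype=bool)
            for col, a in enumerate(anns):
                ii = ridx.get((chrom, a.strand))
                if ii is not None and len(ii):
                    hit[:, col] = ii.overlaps(starts[:, col], starts[:, col] + a.length)
            null += hit.sum(axis=1)
        p_perm, mean, ratio = permutation_pvalue(observed, null)
        n_sub = len(focal)
        exp_in = min(n_sub, int(round(mean)))
        p_fisher = fisher_exact_two_sided(
            [[observed, n_sub - observed], [exp_in, n_sub - exp_in]]
        )
        results.append(
            EnrichmentResult(
                unit=sub, observed=observed, expected_mean=mean, ratio=ratio,
                p=p_fisher, test="fisher", p_perm=p_perm,
                extra={"n_elements": n_sub, "window_bp": window_bp},
            )
        )
    qs = bonferroni([r.p for r in results]) if results else []
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def sd_confound_check(
    sd_intervals: Sequence[tuple[str, int, int]],
    annotations: Sequence[TEAnnotation],
    genes: Sequence[GeneAnnotation],
    layout: GenomeLayout,
    enriched_subfamilies: Sequence[str],
    window_bp: int = 5000,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Could segmental duplications explain an upstream enrichment?

    For each enriched subfamily, take the upstream windows of genes that
    harbor at least one same-orientation element of that subfamily in the
    window, and measure the SD-covered bp there. The null re-places the SD
    intervals uniformly per chromosome. Subfamilies whose regions are
    significantly SD-covered (p < alpha) are flagged — their upstream signal
    may be duplication-driven rather than insertion-driven.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    regions = upstream_regions(genes, layout, window_bp)
    lengths = layout.lengths
    results = []
    for sub in sorted(enriched_subfamilies):
        focal = [a for a in annotations if a.subfamily == sub]
        focal_iv: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for a in focal:
            focal_iv.setdefault((a.chrom, a.strand), []).append((a.start, a.end))
        harbored = [
            (chrom, s, e)
            for chrom, strand, s, e, _ in regions
            if intersect_length([(s, e)], focal_iv.get((chrom, strand), [])) > 0
        ]
        reg_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in harbored:
            reg_by_chrom.setdefault(chrom, []).append((s, e))
        reg_by_chrom = {c: merge(v) for c, v in reg_by_chrom.items()}

        def sd_cov(sd_by_chrom: dict[str, list[tuple[int, int]]]) -> int:
            return sum(
                intersect_length(sd_by_chrom.get(c, []), rs)
                for c, rs in reg_by_chrom.items()
            )

        sd_by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in sd_intervals:
            sd_by_chrom.setdefault(chrom, []).append((s, e))
        observed = sd_cov(sd_by_chrom)

        rng = rng_for(seed, "sd_confound", sub)
        null = np.zeros(n_perm, dtype=np.int64)
        for chrom, ivs in sorted(sd_by_chrom.items()):
            if chrom not in lengths:
                raise ValueError(f"SD interval on unknown chromosome {chrom!r}")
            lens = np.array([e - s for s, e in ivs], dtype=np.int64)
            starts = place_uniform(rng, lens, lengths[chrom], n_perm)
            rs = reg_by_chrom.get(chrom, [])
            if not rs:
                continue
            r_starts = np.array([s for s, _ in rs], dtype=np.int64)
            r_ends = np.array([e for _, e in rs], dtype=np.int64)
            for col, l in enumerate(lens):
                s = starts[:, col][:, None]
                e = s + int(l)
                ov = np.maximum(
                    0, np.minimum(e, r_ends[None, :]) - np.maximum(s, r_starts[None, :])
                )
                null += ov.sum(axis=1)

        p, mean, ratio = permutation_pvalue(observed, null)
        results.append(
            EnrichmentResult(
                unit=sub, observed=observed, expected_mean=mean, ratio=ratio,
                p=p, q=p, test="permutation",
                extra={"flagged": p < alpha, "n_regions": len(harbored)},
            )
        )
    return results


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------


def call_hotspots(
    annotations: Sequence[TEAnnotation],
    layout: GenomeLayout,
    window_bp: int = 100_000,
    percentile: float = 95.0,
    te_filter: Callable[[TEAnnotation], bool] | None = None,
    genes: Sequence[GeneAnnotation] | None = None,
) -> list[HotspotWindow]:
    """Tile chromosomes into windows and flag the top-density tail.

    Density is the proportion of window nucleotides covered by the filtered
    TEs (default: ERVs, i.e. LTR-class elements); a trailing partial window
    is normalised by its actual length. A window is a hotspot when its
    density is >= the ``percentile``-th linear-interpolated quantile of all
    window densities and positive.
    """
    if te_filter is None:
        te_filter = lambda a: a.is_erv
    te_iv = {
        chrom: merge(v)
        for chrom, v in _te_intervals_by_chrom(annotations, te_filter).items()
    }
    gene_iv: dict[str, list[tuple[int, int]]] = {}
    if genes is not None:
        for g in genes:
            gene_iv.setdefault(g.chrom, []).append((g.start, g.end))
        gene_iv = {c: merge(v) for c, v in gene_iv.items()}

    windows: list[HotspotWindow] = []
    for chrom, length in layout.chromosomes:
        for ws in range(0, length, window_bp):
            we = min(ws + window_bp, length)
            erv_bp = intersect_length([(ws, we)], te_iv.get(chrom, []))
            gd = float("nan")
            if genes is not None:
                gd = intersect_length([(ws, we)], gene_iv.get(chrom, [])) / (we - ws)
            windows.append(
                HotspotWindow(
                    chrom=chrom, window=(ws, we),
                    erv_density=erv_bp / (we - ws), gene_density=gd,
                )
            )
    dens = np.array([w.erv_density for w in windows])
    if dens.size == 0:
        return windows
    threshold = float(np.percentile(dens, percentile, method="linear"))
    for w in windows:
        w.is_hotspot = w.erv_density >= threshold and w.erv_density > 0
    return windows


def neighbor_divergence_delta(
    annotations: Sequence[TEAnnotation],
    hotspots: Sequence[HotspotWindow],
    te_filter: Callable[[TEAnnotation], bool] | None = None,
) -> dict:
    """|divergence difference| between neighboring ERVs, inside vs outside hotspots.

    Neighbors are consecutive filtered elements on a chromosome. A pair is
    "inside" when both members intersect a hotspot window, "outside" when
    neither does; mixed pairs are dropped. Two-sided Mann-Whitney U.
    """
    if te_filter is None:
        te_filter = lambda a: a.is_erv
    hot_iv = {
        chrom: IntervalIndex(
            merge([w.window for w in hotspots if w.is_hotspot and w.chrom == chrom]),
            merged=True,
        )
        for chrom in {w.chrom for w in hotspots}
    }

    def in_hot(a: TEAnnotation) -> bool:
        ii = hot_iv.get(a.chrom)
        return ii is not None and len(ii) and bool(ii.overlaps(a.start, a.end))

    inside, outside = [], []
    by_chrom: dict[str, list[TEAnnotation]] = {}
    for a in annotations:
        if te_filter(a):
            by_chrom.setdefault(a.chrom, []).append(a)
    for chrom, anns in by_chrom.items():
        anns.sort(key=lambda a: a.start)
        for u, v in zip(anns, anns[1:]):
            delta = abs(u.divergence_pct - v.divergence_pct)
            hu, hv = in_hot(u), in_hot(v)
            if hu and hv:
                inside.append(delta)
            elif not hu and not hv:
                outside.append(delta)
    if not inside or not outside:
        return {"U": float("nan"), "p": float("nan"), "n_inside": len(inside), "n_outside": len(outside)}
    u, p = mann_whitney_u(inside, outside)
    return {
        "U": u,
        "p": p,
        "n_inside": len(inside),
        "n_outside": len(outside),
        "median_inside": float(np.median(inside)),
        "median_outside": float(np.median(outside)),
    }


def gene_erv_density_association(
    windows: Sequence[HotspotWindow], family: str = "gaussian"
) -> tuple[float, float]:
    """Regression of gene density on ERV density over windows: (coef, p).

    ``gaussian`` fits ordinary least squares on the densities;
    ``binomial-logit`` fits a logit-link GLM treating gene density as a
    proportion. Constant gene density returns (0.0, 1.0).
    """
    import statsmodels.api as sm

    x = np.array([w.erv_density for w in windows])
    y = np.array([w.gene_density for w in windows])
    if np.isnan(y).any():
        raise ValueError("windows lack gene density; pass genes to call_hotspots")
    if np.allclose(y, y[0]):
        return 0.0, 1.0
    X = sm.add_constant(x)
    if family == "gaussian":
        fit = sm.OLS(y, X).fit()
    elif family == "binomial-logit":
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    else:
        raise ValueError(f"unknown family {family!r}")
    return float(fit.params[1]), float(fit.pvalues[1])


def hotspot_gene_content(
    genes: Sequence[GeneAnnotation],
    hotspots: Sequence[HotspotWindow],
    flag: Callable[[GeneAnnotation], bool] | None = None,
) -> EnrichmentResult:
    """Fisher test: are flagged genes (default lineage-specific KZNFs)
    overrepresented inside hotspot windows? A gene is "in" a hotspot when it
    intersects a hotspot window by >= 1 bp."""
    if flag is None:
        flag = lambda g: g.is_kznf and g.is_lineage_specific
    hot_iv = {
        chrom: IntervalIndex(
            merge([w.window for w in hotspots if w.is_hotspot and w.chrom == chrom]),
            merged=True,
        )
        for chrom in {w.chrom for w in hotspots}
    }

    def in_hot(g: GeneAnnotation) -> bool:
        ii = hot_iv.get(g.chrom)
        return ii is not None and len(ii) and bool(ii.overlaps(g.start, g.end))

    fi = fo = oi = oo = 0
    for g in genes:
        inside = in_hot(g)
        if flag(g):
            fi, fo = fi + inside, fo + (not inside)
        else:
            oi, oo = oi + inside, oo + (not inside)
    if fi + fo == 0:
        raise ValueError("no flagged genes")
    p = fisher_exact_two_sided([[fi, fo], [oi, oo]])
    total_in = fi + oi
    total = fi + fo + oi + oo
    expected = (fi + fo) * total_in / total
    return EnrichmentResult(
        unit="flagged_genes", observed=fi, expected_mean=expected,
        ratio=fi / expected if expected > 0 else float("nan"),
        p=p, q=p, test="fisher",
        extra={"table": [[fi, fo], [oi, oo]]},
    )
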