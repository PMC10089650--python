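"""KZNF duplicate-age analysis.

KRAB zinc-finger genes evolve by duplication; the divergence between a gene
and its closest paralog ("nearest duplicate") proxies the age of its last
duplication. Comparing nearest-duplicate divergences of KZNFs inside versus
outside ERV hotspots, and aligning their density peak against within-subfamily
ERVK divergences, asks whether KZNF expansion tracked the ERV expansion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .distribution import HotspotWindow
from .intervals import IntervalIndex, merge
from .io_formats import GeneAnnotation
from .stats import mann_whitney_u


@dataclass
class KZNFRecord:
    gene_id: str
    nearest_duplicate_id: str
    nearest_divergence: float
    in_hotspot: bool = False


def nearest_duplicate_divergence(divergence_matrix: pd.DataFrame) -> list[KZNFRecord]:
    """Per gene, the minimal off-diagonal pairwise divergence and its partner.

    The matrix must be square with identical index/columns (gene ids), a
    zero diagonal, at least two genes, and symmetric to 1e-9. Ties are broken
    toward the lexicographically smaller partner id.
    """
    m = divergence_matrix
    if m.shape[0] != m.shape[1] or list(m.index) != list(m.columns):
        raise ValueError("matrix must be square with matching gene ids")
    if m.shape[0] < 2:
        raise ValueError("need at least two genes")
    vals = m.to_numpy(dtype=float)
    if not np.allclose(np.diag(vals), 0.0):
        raise ValueError("matrix diagonal must be zero")
    if np.nanmax(np.abs(vals - vals.T)) > 1e-9:
        raise ValueError("matrix asymmetric beyond 1e-9 tolerance")

    ids = list(m.index)
    order = np.argsort(np.array(ids, dtype=object), kind="stable")
    records = []
    for i, gid in enumerate(ids):
        best_j = -1
        best_d = np.inf
        for j in order:  # lexicographic partner order => ties go to smaller id
            if j == i:
                continue
            d = vals[i, j]
            if d < best_d:
                best_d = d
                best_j = j
        records.append(
            KZNFRecord(gene_id=gid, nearest_duplicate_id=ids[best_j], nearest_divergence=float(best_d))
        )
    return records


def annotate_hotspot_membership(
    records: Sequence[KZNFRecord],
    genes: Sequence[GeneAnnotation],
    hotspots: Sequence[HotspotWindow],
) -> list[KZNFRecord]:
    """Set ``in_hotspot`` on each record: the gene interval intersects a
    hotspot window by >= 1 bp."""
    gene_by_id = {g.gene_id: g for g in genes}
    hot_iv = {
        chrom: IntervalIndex(
            merge([w.window for w in hotspots if w.is_hotspot and w.chrom == chrom]),
            merged=True,
        )
        for chrom in {w.chrom for w in hotspots}
    }
    out = []
    for r in records:
        g = gene_by_id.get(r.gene_id)
        if g is None:
            raise KeyError(f"gene {r.gene_id} not in gene annotation")
        ii = hot_iv.get(g.chrom)
        in_hot = ii is not None and len(ii) and bool(ii.overlaps(g.start, g.end))
        out.append(
            KZNFRecord(r.gene_id, r.nearest_duplicate_id, r.nearest_divergence, bool(in_hot))
        )
    return out


def dedupe_pairs(records: Sequence[KZNFRecord]) -> list[KZNFRecord]:
    """Keep one record per mutual nearest-duplicate pair (the lexicographically
    first member); non-mutual records are kept as-is."""
    by_id = {r.gene_id: r for r in records}
    out = []
    for r in records:
        partner = by_id.get(r.nearest_duplicate_id)
        mutual = partner is not None and partner.nearest_duplicate_id == r.gene_id
        if mutual and r.gene_id > r.nearest_duplicate_id:
            continue
        out.append(r)
    return out


def compare_hotspot_ages(records: Sequence[KZNFRecord]) -> dict:
    """Two-sided Mann-Whitney U on nearest-duplicate divergence, hotspot vs not."""
    inside = [r.nearest_divergence for r in records if r.in_hotspot]
    outside = [r.nearest_divergence for r in records if not r.in_hotspot]
    if not inside or not outside:
        raise ValueError("both hotspot and non-hotspot groups must be non-empty")
    u, p = mann_whitney_u(inside, outside)
    return {
        "U": u,
        "p": p,
        "n_inside": len(inside),
        "n_outside": len(outside),
        "median_inside": float(np.median(inside)),
        "median_outside": float(np.median(outside)),
    }


def kde_peaks(
    samples_by_group: Mapping[str, Sequence[float]], grid_step: float = 0.1
) -> dict[str, float]:
    """Gaussian KDE (Scott bandwidth) peak location per group.

    The density is evaluated on [0, max + 3*bandwidth] at ``grid_step``
    spacing; the peak is the argmax (ties resolved toward the lower value by
    taking the first maximum). A degenerate group (single value or zero
    variance) peaks at that value.
    """
    peaks = {}
    for group, samples in samples_by_group.items():
        x = np.asarray(list(samples), dtype=float)
        if x.size == 0:
            raise ValueError(f"group {group!r} is empty")
        if x.size == 1 or np.allclose(x, x[0]):
            peaks[group] = float(x[0])
            continue
        kde = gaussian_kde(x)  # Scott's rule by default
        bw = kde.factor * x.std(ddof=1)
        grid = np.arange(0.0, x.max() + 3 * bw + grid_step, grid_step)
        dens = kde(grid)
        # ties (within float noise) resolve to the lower location
        near_max = np.nonzero(dens >= dens.max() * (1.0 - 1e-9))[0]
        peaks[group] = float(grid[int(near_max[0])])
    return peaks
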