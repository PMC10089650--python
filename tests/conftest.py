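"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings

from teeco.io_formats import GenomeLayout, TEAnnotation, resolve_overlaps
from teeco.synthetic_data import generate, rodentlike_config

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def mk_te(
    element_id=0,
    chrom="chr1",
    start=0,
    end=100,
    strand="+",
    subfamily="SUB",
    te_class="LTR",
    superfamily="ERVK",
    lineage_specific=True,
    divergence_pct=10.0,
    cons_start=1,
    cons_end=None,
    cons_remaining=0,
) -> TEAnnotation:
    """Annotation factory with consistent consensus coordinates by default."""
    if cons_end is None:
        cons_end = cons_start + (end - start) - 1
    return TEAnnotation(
        element_id=element_id, chrom=chrom, start=start, end=end, strand=strand,
        subfamily=subfamily, te_class=te_class, superfamily=superfamily,
        lineage_specific=lineage_specific, divergence_pct=divergence_pct,
        cons_start=cons_start, cons_end=cons_end, cons_remaining=cons_remaining,
    )


@pytest.fixture(scope="session")
def small_layout() -> GenomeLayout:
    return GenomeLayout(chromosomes=(("chr1", 1_000_000), ("chr2", 500_000)))


@pytest.fixture(scope="session")
def rodentlike_dataset():
    """One bundled small genome shared by the slower end-to-end tests."""
    ds = generate(rodentlike_config(seed=1))
    return ds


@pytest.fixture(scope="session")
def rodentlike_resolved(rodentlike_dataset):
    return resolve_overlaps(rodentlike_dataset.annotations)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately written in a different style from the
# library code paths they check)
# ---------------------------------------------------------------------------


def kimura_site_oracle(consensus: str, copy: str, cpg: bool = True) -> float:
    """Brute-force per-site classification of an aligned pair.

    Walks the alignment site by site, tags each consensus position that opens
    a CpG (C followed by G after skipping gaps), classifies every comparable
    mismatch as transition/transversion, applies the CpG weighting rules, and
    evaluates the Kimura formula directly.
    """
    consensus, copy = consensus.upper(), copy.upper()
    ts_pairs = {"AG", "GA", "CT", "TC"}

    cpg_partner = {}
    cols = [i for i, b in enumerate(consensus) if b != "-"]
    for a, b in zip(cols, cols[1:]):
        if consensus[a] == "C" and consensus[b] == "G":
            cpg_partner[a] = b
            cpg_partner[b] = a

    n = ts = tv = 0
    counted_cpg = set()
    for i in range(len(consensus)):
        x, y = consensus[i], copy[i]
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if x + y in ts_pairs:
            if cpg and i in cpg_partner:
                j = cpg_partner[i]
                if j in counted_cpg:
                    continue  # partner already accounted for this CpG
                partner_ts = (
                    consensus[j] in "ACGT"
                    and copy[j] in "ACGT"
                    and copy[j] != consensus[j]
                    and consensus[j] + copy[j] in ts_pairs
                )
                ts += 1.0 if partner_ts else 0.1
                counted_cpg.add(i)
                counted_cpg.add(j)
            else:
                ts += 1
        else:
            tv += 1
    p, q = ts / n, tv / n
    return -50.0 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q))


def random_aligned_pair(rng: np.random.Generator, length: int = 400):
    """Random consensus/copy alignment with substitutions, gaps and Ns, kept
    far from Kimura saturation."""
    bases = np.array(list("ACGT"))
    cons = rng.choice(bases, size=length)
    copy = cons.copy()
    ts_map = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv_map = {"A": "C", "G": "T", "C": "G", "T": "A"}
    for i in range(length):
        u = rng.random()
        if u < 0.08:
            copy[i] = ts_map[cons[i]]
        elif u < 0.12:
            copy[i] = tv_map[cons[i]]
    cons = cons.tolist()
    copy = copy.tolist()
    for i in rng.choice(length, size=max(1, length // 50), replace=False):
        which = rng.random()
        if which < 0.4:
            cons[i] = "-"
        elif which < 0.8:
            copy[i] = "-"
        else:
            copy[i] = "N"
    return "".join(cons), "".join(copy)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of tables with fixed margins,
    summing hypergeometric probabilities <= the observed table's."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def table_prob(k: int) -> float:
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = table_prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = table_prob(k)
        if pk <= p_obs * (1 + 1e-12):
            total += pk
    return min(1.0, total)


def mwu_enumeration_oracle(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney by enumerating every split of the pooled data
    and computing U from pairwise comparisons (ties count half)."""
    import itertools

    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(xs, ys):
        u = 0.0
        for xi in xs:
            for yi in ys:
                if xi > yi:
                    u += 1.0
                elif xi == yi:
                    u += 0.5
        return u

    u_obs = u_stat(list(x), list(y))
    idx = range(len(pooled))
    us = []
    for combo in itertools.combinations(idx, nx):
        sel = set(combo)
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in idx if i not in sel]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    eps = 1e-9
    p = min(1.0, 2 * min(np.mean(us <= u_obs + eps), np.mean(us >= u_obs - eps)))
    return u_obs, float(p)
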