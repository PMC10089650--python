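"""ERV structural analysis: LTR pair identity dating and autonomy calls.

An ERV inserts with two identical long terminal repeats, so the percent
identity between an element's 5' and 3' LTRs estimates its insertion age.
Autonomy is judged from coding capacity: a subfamily is called nonautonomous
only on solid evidence — at least five full-length, gap-free copies, none of
which contains a qualifying ORF. Machinery screening is restricted to LINE
elements longer than 2,700 bp and LTR elements longer than 5,000 bp, the
sizes below which complete retroelement machinery cannot fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .io_formats import TEAnnotation

_NUC = set("ACGTN")

LINE_MACHINERY_MIN_BP = 2700
LTR_MACHINERY_MIN_BP = 5000


@dataclass(frozen=True)
class LTRPair:
    element_id: int
    ltr5: tuple[int, int]  # interval on the element, 0-based half-open
    ltr3: tuple[int, int]
    identity_pct: float
    aligned_len: int


@dataclass(frozen=True)
class ORF:
    start: int  # 0-based on the forward sequence
    end: int
    strand: str
    frame: int
    length_codons: int


@dataclass
class AutonomyCall:
    subfamily: str
    status: str  # {autonomous, nonautonomous, ambiguous}
    n_fulllength_gapfree: int
    orf_evidence: list[tuple[int, int, str]]  # (element_id, orf_length_codons, label)


@dataclass(frozen=True)
class CopyRecord:
    """One subfamily copy as presented to classify_autonomy.

    ``seq`` may be None when only annotation-level evidence exists; the ORF
    screen then relies on ``orf_labels`` alone (an empty label set means no
    known coding capacity).
    """

    element_id: int
    seq: str | None
    has_gap: bool
    is_fulllength: bool
    orf_labels: tuple[str, ...] = ()


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


def find_ltr_pair(
    element_seq: str, min_ltr_len: int = 100, min_identity: float = 80.0
) -> LTRPair | None:
    """Best local alignment between the element's prefix and suffix windows.

    The window is ``min(2000, len/3)`` bp at each end. Returns None when the
    best alignment is shorter than ``min_ltr_len`` columns or below
    ``min_identity`` percent matching columns.
    """
    seq = element_seq.upper()
    if set(seq) - _NUC:
        raise ValueError("element sequence contains non-nucleotide characters")
    if len(seq) <= 2 * min_ltr_len:
        raise ValueError("sequence too short for two LTRs of min_ltr_len")
    window = min(2000, len(seq) // 3)
    prefix = seq[:window]
    suffix_off = len(seq) - window
    suffix = seq[suffix_off:]

    aln = _aligner().align(prefix, suffix)
    if len(aln) == 0:
        return None
    best = aln[0]
    a_idx, b_idx = best.aligned  # blocks on prefix / suffix
    if len(a_idx) == 0:
        return None
    matches = 0
    cols = 0
    for (as_, ae), (bs, be) in zip(a_idx, b_idx):
        seg_a = prefix[as_:ae]
        seg_b = suffix[bs:be]
        matches += sum(1 for x, y in zip(seg_a, seg_b) if x == y)
        cols += ae - as_
    # gap columns between aligned blocks
    for k in range(1, len(a_idx)):
        cols += (a_idx[k][0] - a_idx[k - 1][1]) + (b_idx[k][0] - b_idx[k - 1][1])
    if cols < min_ltr_len:
        return None
    identity = 100.0 * matches / cols
    if identity < min_identity:
        return None
    return LTRPair(
        element_id=-1,
        ltr5=(int(a_idx[0][0]), int(a_idx[-1][1])),
        ltr3=(suffix_off + int(b_idx[0][0]), suffix_off + int(b_idx[-1][1])),
        identity_pct=identity,
        aligned_len=int(cols),
    )


def ltr_identity_distribution(
    pairs: Sequence[LTRPair], subfamily_of: Mapping[int, str]
) -> pd.DataFrame:
    """Per-subfamily n/median/quartiles of LTR pair identity.

    ``subfamily_of`` maps element_id -> subfamily. Subfamilies named in the
    map but lacking any LTR pair are omitted with a warning.
    """
    rows: dict[str, list[float]] = {}
    for p in pairs:
        sub = subfamily_of.get(p.element_id)
        if sub is None:
            raise KeyError(f"element {p.element_id} missing from subfamily map")
        rows.setdefault(sub, []).append(p.identity_pct)
    missing = set(subfamily_of.values()) - set(rows)
    if missing:
        warnings.warn(f"subfamilies without LTR pairs omitted: {sorted(missing)}")
    out = [
        {
            "subfamily": sub,
            "n": len(vals),
            "median": float(np.median(vals)),
            "q25": float(np.percentile(vals, 25)),
            "q75": float(np.percentile(vals, 75)),
        }
        for sub, vals in sorted(rows.items())
    ]
    return pd.DataFrame(out, columns=["subfamily", "n", "median", "q25", "q75"])


_STOPS = {"TAA", "TAG", "TGA"}


def _orfs_one_strand(seq: str, min_len_codons: int, strand: str, seq_len: int) -> list[ORF]:
    out = []
    for frame in range(3):
        start_codon: int | None = None
        for pos in range(frame, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in _STOPS:
                if start_codon is not None:
                    n_codons = (pos - start_codon) // 3
                    span = seq[start_codon : pos + 3]
                    if n_codons >= min_len_codons and "N" not in span:
                        s, e = start_codon, pos + 3
                        if strand == "-":
                            s, e = seq_len - e, seq_len - s
                        out.append(ORF(s, e, strand, frame, n_codons))
                start_codon = None
            elif codon == "ATG" and start_codon is None:
                start_codon = pos
    return out


def find_orfs(seq: str, min_len_codons: int = 100, frames: str = "given-strand") -> list[ORF]:
    """Maximal ATG->stop open reading frames of at least ``min_len_codons``.

    Length counts coding codons (ATG included, stop excluded). ORFs spanning
    an ambiguous base (N) are rejected. ``frames`` is ``given-strand`` (3
    forward frames) or ``six-frame``. Coordinates are on the input sequence.
    """
    s = seq.upper()
    if set(s) - _NUC:
        raise ValueError("sequence contains non-nucleotide characters")
    orfs = _orfs_one_strand(s, min_len_codons, "+", len(s))
    if frames == "six-frame":
        rc = str(Seq(s).reverse_complement())
        orfs += _orfs_one_strand(rc, min_len_codons, "-", len(s))
    elif frames != "given-strand":
        raise ValueError(f"unknown frames mode {frames!r}")
    return sorted(orfs, key=lambda o: (o.start, o.end))


def is_full_length(
    ann: TEAnnotation, consensus_length: int, length_tol: float = 0.10, end_tol_bp: int = 20
) -> bool:
    """Full-length call: length within +/-10% of consensus and both consensus
    ends reached to within 20 bp."""
    if consensus_length <= 0:
        raise ValueError("consensus_length must be positive")
    within = abs(ann.length - consensus_length) <= length_tol * consensus_length
    return within and ann.cons_start <= end_tol_bp and ann.cons_remaining <= end_tol_bp


def classify_autonomy(
    subfamily: str,
    copies: Sequence[CopyRecord],
    min_copies: int = 5,
    orf_min_codons: int = 200,
) -> AutonomyCall:
    """Classify one ERV subfamily as autonomous / nonautonomous / ambiguous.

    * autonomous: some full-length copy carries both gag and pro/pol labels
      (from annotation, or any pair of qualifying ORFs when only sequence is
      available is NOT sufficient — labels are required for autonomy);
    * nonautonomous: at least ``min_copies`` full-length gap-free copies and
      none of them carries a qualifying ORF (label or >=``orf_min_codons``
      ORF found in its sequence);
    * ambiguous otherwise.
    """
    if not copies:
        raise ValueError(f"subfamily {subfamily}: no copies supplied")

    evidence: list[tuple[int, int, str]] = []

    def qualifying_orfs(c: CopyRecord) -> list[tuple[int, int, str]]:
        hits = [(c.element_id, 0, lab) for lab in c.orf_labels]
        if c.seq is not None:
            hits += [
                (c.element_id, o.length_codons, "orf")
                for o in find_orfs(c.seq, min_len_codons=orf_min_codons)
            ]
        return hits

    full = [c for c in copies if c.is_fulllength]
    eligible = [c for c in full if not c.has_gap]

    labels_by_copy = {c.element_id: {l.lower() for l in c.orf_labels} for c in full}
    autonomous = any(
        "gag" in labs and ({"pol", "pro-pol", "pro", "propol"} & labs)
        for labs in labels_by_copy.values()
    )

    orf_free = True
    for c in eligible:
        hits = qualifying_orfs(c)
        evidence.extend(hits)
        if hits:
            orf_free = False

    if autonomous:
        status = "autonomous"
    elif len(eligible) >= min_copies and orf_free:
        status = "nonautonomous"
    else:
        status = "ambiguous"
    return AutonomyCall(
        subfamily=subfamily,
        status=status,
        n_fulllength_gapfree=len(eligible),
        orf_evidence=evidence,
    )


def machinery_candidates(annotations: Iterable[TEAnnotation]) -> list[TEAnnotation]:
    """Elements long enough to encode their own machinery: LINEs > 2,700 bp
    and LTR elements > 5,000 bp."""
    return [
        a
        for a in annotations
        if (a.te_class == "LINE" and a.length > LINE_MACHINERY_MIN_BP)
        or (a.te_class == "LTR" and a.length > LTR_MACHINERY_MIN_BP)
    ]
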