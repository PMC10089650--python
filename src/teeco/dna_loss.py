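"""DNA-loss coefficient from extant ancestral DNA.

Under exponential decay of ancestral sequence, E = A * exp(-k t): E is the
extant ancestral DNA in the genome today (bp), A the ancestral assembly size
(bp) and t the elapsed time (million years), giving the per-My loss
coefficient k = ln(A / E) / t. The conventional comparative values are
A = 2.8 Gb and t = 100 My for the murid/cricetid comparison this package
targets; both are plain arguments here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from .io_formats import TEAnnotation
from .intervals import total_length

logger = logging.getLogger(__name__)

DEFAULT_A_BP = 2.8e9
DEFAULT_T_MY = 100.0


@dataclass(frozen=True)
class LossCoefficient:
    E_bp: float
    A_bp: float
    t_my: float
    k: float


def compute_k(E_bp: float, A_bp: float = DEFAULT_A_BP, t_my: float = DEFAULT_T_MY) -> LossCoefficient:
    """k = ln(A/E)/t. Positive k means net loss of ancestral DNA."""
    if E_bp <= 0 or A_bp <= 0 or t_my <= 0:
        raise ValueError("E_bp, A_bp and t_my must all be positive")
    k = math.log(A_bp / E_bp) / t_my
    return LossCoefficient(E_bp=E_bp, A_bp=A_bp, t_my=t_my, k=k)


def extant_ancestral_dna(
    annotations: Sequence[TEAnnotation],
    assembly_bp: int,
    ancient_labels: set[str] = frozenset(),
    mode: str = "conventional",
) -> float:
    """Extant ancestral DNA E (bp) from a repeat annotation.

    Two readings are supported and both are logged:

    * ``conventional``: E = assembly size - lineage-specific TE bp — every
      base not attributable to lineage-specific insertions is ancestral.
    * ``literal``: E = ancient-TE bp - lineage-specific TE bp, i.e. the
      ancestral proxy restricted to annotated TE sequence. This difference
      can be negative in TE-expansive lineages, in which case an error
      directs the caller to the conventional reading.

    Ancient means subfamily in ``ancient_labels``; lineage-specific uses the
    annotation's own flag. bp figures are union lengths per category.
    """
    lineage_iv: dict[str, list] = {}
    ancient_iv: dict[str, list] = {}
    for a in annotations:
        if a.lineage_specific:
            lineage_iv.setdefault(a.chrom, []).append((a.start, a.end))
        if a.subfamily in ancient_labels:
            ancient_iv.setdefault(a.chrom, []).append((a.start, a.end))
    lineage_bp = sum(total_length(v) for v in lineage_iv.values())
    ancient_bp = sum(total_length(v) for v in ancient_iv.values())

    conventional = assembly_bp - lineage_bp
    literal = ancient_bp - lineage_bp
    logger.info(
        "extant ancestral DNA: conventional=%d bp (assembly %d - lineage-specific %d); "
        "literal=%d bp (ancient %d - lineage-specific %d)",
        conventional, assembly_bp, lineage_bp, literal, ancient_bp, lineage_bp,
    )
    if mode == "conventional":
        return float(conventional)
    if mode == "literal":
        if literal < 0:
            raise ValueError(
                "literal reading (ancient - lineage-specific TE bp) is negative; "
                "use mode='conventional'"
            )
        return float(literal)
    raise ValueError(f"unknown mode {mode!r}")
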