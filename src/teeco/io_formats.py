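"""Readers, writers and coordinate normalisation for repeat and gene annotations.

Internal convention everywhere in this package: 0-based half-open genomic
intervals ``[start, end)``. RepeatMasker ``.out`` and GFF3 are 1-based
inclusive; the conversion happens here, at the boundary, and nowhere else.

Consensus coordinates stay 1-based inclusive (that is how the ``.out`` format
carries them) but are normalised so that ``cons_start <= cons_end`` on both
strands; the minus-strand "(left) end begin" column order is undone on read.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import merge, total_length

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA", "other")


class FormatError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths plus optional assembly-gap intervals."""

    chromosomes: tuple[tuple[str, int], ...]
    gap_intervals: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for n, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {n} has non-positive length")
        lengths = dict(self.chromosomes)
        for chrom, s, e in self.gap_intervals:
            if chrom not in lengths or not (0 <= s < e <= lengths[chrom]):
                raise ValueError(f"gap interval {chrom}:{s}-{e} outside chromosome bounds")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass
class TEAnnotation:
    """One annotated repeat fragment with genomic and consensus coordinates."""

    element_id: int
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    subfamily: str
    te_class: str
    superfamily: str = ""
    lineage_specific: bool = False
    divergence_pct: float = 0.0
    cons_start: int = 1  # 1-based inclusive, on the subfamily consensus
    cons_end: int = 1
    cons_remaining: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"element {self.element_id}: start >= end ({self.start} >= {self.end})")
        if self.cons_start > self.cons_end:
            raise ValueError(f"element {self.element_id}: cons_start > cons_end")
        if self.divergence_pct < 0:
            raise ValueError(f"element {self.element_id}: negative divergence")
        if self.strand not in ("+", "-"):
            raise ValueError(f"element {self.element_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_erv(self) -> bool:
        """LTR-class elements stand for ERVs (incl. nonautonomous MaLRs)."""
        return self.te_class == "LTR"


@dataclass
class GeneAnnotation:
    """Gene interval with strand, biotype, CDS structure and analysis flags."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "other"  # {coding, lncRNA, other}
    cds_intervals: tuple[tuple[int, int], ...] = ()
    is_kznf: bool = False
    is_lineage_specific: bool = False

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        for s, e in self.cds_intervals:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: CDS {s}-{e} outside gene body")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# RepeatMasker .out dialect
# ---------------------------------------------------------------------------

_CLASS_MAP = {"LINE": "LINE", "SINE": "SINE", "LTR": "LTR", "DNA": "DNA", "RC": "DNA"}


def _split_class_family(token: str) -> tuple[str, str]:
    parts = token.split("/", 1)
    te_class = _CLASS_MAP.get(parts[0], "other")
    superfamily = parts[1] if len(parts) == 2 else parts[0]
    return te_class, superfamily


def _paren(tok: str) -> int:
    return int(tok.strip("()"))


def read_te_annotations(
    path,
    dialect: str = "out",
    layout: GenomeLayout | None = None,
    lineage_prefixes: Sequence[str] = ("Pman",),
) -> list[TEAnnotation]:
    """Read repeat annotations from a RepeatMasker ``.out`` file or a teeco TSV.

    ``.out`` genomic coordinates (1-based inclusive) are converted to 0-based
    half-open; minus-strand consensus columns ("(left) end begin") are
    normalised so ``cons_start <= cons_end``. Records are returned sorted by
    (chrom, start, end). ``lineage_prefixes`` marks subfamilies whose names
    start with any prefix as lineage-specific (the ``.out`` format itself
    carries no such flag; the TSV dialect round-trips it explicitly).
    """
    path = Path(path)
    if dialect == "tsv":
        records = read_table(path, TEAnnotation)
    elif dialect == "out":
        records = _read_out(path, lineage_prefixes)
    else:
        raise ValueError(f"unsupported dialect {dialect!r}")

    if layout is not None:
        lengths = layout.lengths
        for r in records:
            if r.chrom not in lengths:
                raise FormatError(f"unknown chromosome {r.chrom!r} for element {r.element_id}")
            if r.end > lengths[r.chrom]:
                raise FormatError(f"element {r.element_id} extends past end of {r.chrom}")
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def _read_out(path: Path, lineage_prefixes: Sequence[str]) -> list[TEAnnotation]:
    records: list[TEAnnotation] = []
    next_id = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            # 3-line header: starts with column labels or dashes
            if line.lower().startswith(("sw", "score", "--")):
                continue
            tok = line.split()
            if len(tok) < 14:
                raise FormatError(f"{path}:{lineno}: expected >=14 columns, got {len(tok)}")
            try:
                div = float(tok[1])
                chrom = tok[4]
                qstart, qend = int(tok[5]), int(tok[6])
                strand = "+" if tok[8] == "+" else "-"
                subfamily = tok[9]
                te_class, superfamily = _split_class_family(tok[10])
                if strand == "+":
                    cons_start, cons_end, cons_rem = int(tok[11]), int(tok[12]), _paren(tok[13])
                else:
                    # minus strand column order: (left) end begin
                    cons_rem, cons_end, cons_start = _paren(tok[11]), int(tok[12]), int(tok[13])
                elem_id = int(tok[14]) if len(tok) > 14 and tok[14].lstrip("-").isdigit() else next_id
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if qend < qstart:
                raise FormatError(f"{path}:{lineno}: genomic end < start ({qend} < {qstart})")
            if cons_end < cons_start:
                raise FormatError(f"{path}:{lineno}: consensus end < start after normalisation")
            records.append(
                TEAnnotation(
                    element_id=elem_id,
                    chrom=chrom,
                    start=qstart - 1,
                    end=qend,
                    strand=strand,
                    subfamily=subfamily,
                    te_class=te_class,
                    superfamily=superfamily,
                    lineage_specific=any(subfamily.startswith(p) for p in lineage_prefixes),
                    divergence_pct=div,
                    cons_start=cons_start,
                    cons_end=cons_end,
                    cons_remaining=cons_rem,
                )
            )
            next_id = max(next_id, elem_id) + 1
    return records


def write_te_out(records: Iterable[TEAnnotation], path) -> Path:
    """Emit records in the RepeatMasker ``.out`` dialect (with the 3-line header)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            "   SW   perc perc perc  query      position in query           matching"
            "       repeat              position in repeat\n"
            "score   div. del. ins.  sequence    begin     end    (left)    repeat"
            "         class/family         begin  end (left)   ID\n\n"
        )
        for r in records:
            cls = r.te_class if r.te_class != "other" else "Unknown"
            fam = f"{cls}/{r.superfamily}" if r.superfamily and r.superfamily != cls else cls
            if r.strand == "+":
                rep = f"{r.cons_start} {r.cons_end} ({r.cons_remaining})"
                strand = "+"
            else:
                rep = f"({r.cons_remaining}) {r.cons_end} {r.cons_start}"
                strand = "C"
            fh.write(
                f"  100 {r.divergence_pct:5.2f}  0.0  0.0  {r.chrom} {r.start + 1} {r.end} (0) "
                f"{strand} {r.subfamily} {fam} {rep} {r.element_id}\n"
            )
    return path


# ---------------------------------------------------------------------------
# Overlap resolution
# ---------------------------------------------------------------------------


def resolve_overlaps(annotations: Sequence[TEAnnotation], min_overlap_bp: int = 1) -> list[TEAnnotation]:
    """Keep the longer element wherever two annotations overlap by >= ``min_overlap_bp``.

    Ties broken by lower divergence, then smaller start. Elements are removed
    whole (never truncated), so the result is overlap-free at the threshold
    and idempotent under re-application. Input must be sorted by (chrom, start).
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    order = sorted(
        range(len(annotations)),
        key=lambda i: (-(annotations[i].length), annotations[i].divergence_pct, annotations[i].chrom, annotations[i].start),
    )
    kept_by_chrom: dict[str, list[tuple[int, int]]] = {}
    keep = [False] * len(annotations)
    for i in order:
        a = annotations[i]
        kept = kept_by_chrom.setdefault(a.chrom, [])
        conflict = any(min(a.end, e) - max(a.start, s) >= min_overlap_bp for s, e in kept)
        if not conflict:
            keep[i] = True
            kept.append((a.start, a.end))
    return [a for i, a in enumerate(annotations) if keep[i]]


# ---------------------------------------------------------------------------
# Genes
# ---------------------------------------------------------------------------


def read_genes(
    path,
    format: str = "gff3",
    kznf_attr: str = "kznf",
    lineage_attr: str = "lineage_specific",
    biotype_attr: str = "gene_biotype",
) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 (genes + CDS children) or BED6.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    KZNF / lineage flags are read from the named attribute keys (values
    true/1/yes, case-insensitive). BED6 yields biotype ``other`` and no CDS.
    """
    path = Path(path)
    if format == "bed":
        return _read_genes_bed(path)
    if format != "gff3":
        raise ValueError(f"unsupported gene format {format!r}")

    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    truthy = {"true", "1", "yes"}

    def flag(feat, key):
        vals = feat.attributes.get(key, [])
        return bool(vals) and vals[0].lower() in truthy

    genes: list[GeneAnnotation] = []
    for feat in db.features_of_type("gene"):
        biotype_raw = (feat.attributes.get(biotype_attr, ["other"]) or ["other"])[0]
        biotype = {"protein_coding": "coding", "coding": "coding", "lncRNA": "lncRNA"}.get(biotype_raw, "other")
        cds = tuple(
            sorted((c.start - 1, c.end) for c in db.children(feat, featuretype="CDS"))
        )
        if feat.strand not in ("+", "-"):
            raise FormatError(f"gene {feat.id}: missing strand")
        genes.append(
            GeneAnnotation(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                biotype=biotype,
                cds_intervals=cds,
                is_kznf=flag(feat, kznf_attr),
                is_lineage_specific=flag(feat, lineage_attr),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes


def _read_genes_bed(path: Path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            tok = line.split("\t")
            if len(tok) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 requires 6 columns")
            genes.append(
                GeneAnnotation(
                    gene_id=tok[3],
                    chrom=tok[0],
                    start=int(tok[1]),
                    end=int(tok[2]),
                    strand=tok[5],
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes


def write_genes_gff3(genes: Iterable[GeneAnnotation], path) -> Path:
    """Emit genes (+ CDS children) as GFF3, inverting read_genes' conventions."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            biotype = {"coding": "protein_coding"}.get(g.biotype, g.biotype)
            attrs = (
                f"ID={g.gene_id};gene_biotype={biotype};"
                f"kznf={'true' if g.is_kznf else 'false'};"
                f"lineage_specific={'true' if g.is_lineage_specific else 'false'}"
            )
            fh.write(f"{g.chrom}\tteeco\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            for i, (s, e) in enumerate(g.cds_intervals):
                fh.write(
                    f"{g.chrom}\tteeco\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )
    return path


# ---------------------------------------------------------------------------
# BED intervals (segmental duplications etc.) and layout
# ---------------------------------------------------------------------------


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            tok = line.split("\t")
            if len(tok) < 3:
                raise FormatError(f"{path}:{lineno}: BED requires >=3 columns")
            s, e = int(tok[1]), int(tok[2])
            if e <= s:
                raise FormatError(f"{path}:{lineno}: end <= start")
            out.append((tok[0], s, e))
    return sorted(out)


def write_bed_intervals(intervals: Iterable[tuple[str, int, int]], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    return path


def read_layout(path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t")
    chroms = tuple((str(r.chrom), int(r.length_bp)) for r in df.itertuples())
    return GenomeLayout(chromosomes=chroms)


def write_layout(layout: GenomeLayout, path) -> Path:
    path = Path(path)
    pd.DataFrame(layout.chromosomes, columns=["chrom", "length_bp"]).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Generic round-trip TSV for record dataclasses
# ---------------------------------------------------------------------------

_TUPLE_FIELDS = {"cds_intervals"}


def _encode(value):
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, tuple):
        return ";".join(f"{s}-{e}" for s, e in value) or "."
    return str(value)


def _decode(text: str, typ, name: str):
    if name in _TUPLE_FIELDS:
        if text == ".":
            return ()
        return tuple(tuple(int(x) for x in part.split("-")) for part in text.split(";"))
    if typ is bool or typ == "bool":
        return text == "true"
    if typ is int or typ == "int":
        return int(text)
    if typ is float or typ == "float":
        return float(text)
    return text


def write_table(records: Sequence, path, record_type=None) -> Path:
    """Round-trip-exact TSV for any of the package's record dataclasses.

    An empty list writes a header-only file (pass ``record_type`` so the
    header is known; otherwise an empty file is written).
    """
    path = Path(path)
    if not records:
        if record_type is not None:
            path.write_text("\t".join(f.name for f in dataclasses.fields(record_type)) + "\n")
        else:
            path.write_text("")
        return path
    fields = [f.name for f in dataclasses.fields(records[0])]
    with open(path, "w") as fh:
        fh.write("\t".join(fields) + "\n")
        for r in records:
            fh.write("\t".join(_encode(getattr(r, name)) for name in fields) + "\n")
    return path


def read_table(path, record_type) -> list:
    """Inverse of :func:`write_table` for the given dataclass type."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return []
    lines = text.splitlines()
    header = lines[0].split("\t")
    fieldmap = {f.name: f for f in dataclasses.fields(record_type)}
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        vals = line.split("\t")
        if len(vals) != len(header):
            raise FormatError(f"{path}:{lineno}: column count mismatch")
        kwargs = {}
        for name, raw in zip(header, vals):
            f = fieldmap[name]
            typ = f.type if isinstance(f.type, type) else str(f.type)
            kwargs[name] = _decode(raw, typ, name)
        records.append(record_type(**kwargs))
    return records


def te_annotations_to_frame(annotations: Sequence[TEAnnotation]) -> pd.DataFrame:
    """Convenience DataFrame view (analysis modules use it for vectorised work)."""
    return pd.DataFrame([dataclasses.asdict(a) for a in annotations])


def class_occupancy_bp(annotations: Sequence[TEAnnotation]) -> dict[str, int]:
    """Union bp per te_class (per chromosome, then summed)."""
    by: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for a in annotations:
        by.setdefault(a.te_class, {}).setdefault(a.chrom, []).append((a.start, a.end))
    return {
        cls: sum(total_length(ivs) for ivs in chroms.values())
        for cls, chroms in by.items()
    }
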