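"""Readers and writers for the external formats the pipeline touches.

Formats handled:

* Bismark-style cytosine report ("CX report"): 7-column TSV with one row
  per cytosine — chromosome, 1-based position, strand, methylated read
  count, unmethylated read count, sequence context (CG/CHG/CHH) and
  trinucleotide.
* Gene / transposable-element annotations as GFF3 (1-based inclusive) or
  BED (0-based half-open), normalised on read to 0-based half-open.
* TE insertion/deletion polymorphism calls as a BED-like table
  (chrom, start, end, type, family, comma-separated carrier lines).
* SNP genotype calls as a 3+N-column TSV or a VCF (GT field only,
  collapsed to reference / alternate / missing per line).
* Per-context tile methylation tracks as bedGraph, and full tile tables
  as TSV.

Coordinate conventions: every interval in the package is 0-based
half-open.  Cytosine positions keep the 1-based convention of the report
they come from; they are converted where tiles are formed (see
:mod:`tilemeth.tiling`).  Zero-coverage cytosines are retained on read so
that "cytosines with coverage" filters are applied downstream, not at
parse time.  Strands are never collapsed: each strand's cytosine is an
independent record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

#: The three cytosine sequence contexts (H = A, C or T).
CONTEXTS = ("CG", "CHG", "CHH")

#: Genotype call states for SNP tables.
CALL_STATES = ("reference", "alternate", "missing")

_H = set("ACT")


class FormatError(ValueError):
    """A file did not conform to its declared format."""


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine's strand, sequence context and read counts.

    ``pos`` is 1-based, as in the cytosine report.  ``count_meth`` /
    ``count_unmeth`` are read counts supporting the methylated /
    unmethylated state.
    """

    chrom: str
    pos: int
    strand: str
    count_meth: int
    count_unmeth: int
    context: str
    trinucleotide: str

    @property
    def coverage(self) -> int:
        return self.count_meth + self.count_unmeth


@dataclass(frozen=True)
class AnnotationFeature:
    """A gene or TE annotation interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    kind: str  # "gene" or "TE"
    family: str  # TE superfamily code (e.g. DTT, RLC, RLX); empty for genes
    id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"feature {self.id!r}: start {self.start} >= end {self.end}"
            )
        if self.kind == "gene" and self.family:
            raise FormatError(f"gene feature {self.id!r} carries a TE family")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SNPRecord:
    """A single-nucleotide polymorphism with per-line call states.

    ``calls`` maps line name to one of ``reference``, ``alternate`` or
    ``missing``.  ``pos`` is 1-based.
    """

    chrom: str
    pos: int
    calls: dict = field(hash=False)

    def __post_init__(self) -> None:
        if not any(v != "missing" for v in self.calls.values()):
            raise FormatError(f"SNP {self.chrom}:{self.pos} has no non-missing call")


@dataclass(frozen=True)
class TEPolymorphism:
    """A TE insertion or deletion relative to the reference, 0-based half-open.

    Insertions may be zero-length (the point of insertion into the
    reference); deletions span the deleted element.  ``lines`` is the set
    of line names carrying the variant.
    """

    chrom: str
    start: int
    end: int
    type: str  # "insertion" or "deletion"
    family: str
    lines: frozenset

    def __post_init__(self) -> None:
        if self.type not in ("insertion", "deletion"):
            raise FormatError(f"unknown TE polymorphism type {self.type!r}")
        if self.start > self.end:
            raise FormatError(f"TE polymorphism start {self.start} > end {self.end}")
        if self.type == "deletion" and self.start == self.end:
            raise FormatError("deletion must span at least 1 bp")
        if not self.lines:
            raise FormatError("TE polymorphism carried by no line")


def _check_context_trinucleotide(context: str, tri: str) -> bool:
    """True when ``tri`` is compatible with ``context`` (N suppresses the check)."""
    if "N" in tri or len(tri) != 3:
        return True
    if tri[0] != "C":
        return False
    if context == "CG":
        return tri[1] == "G"
    if context == "CHG":
        return tri[1] in _H and tri[2] == "G"
    return tri[1] in _H and tri[2] in _H  # CHH


def read_cx_report(path) -> list[CytosineRecord]:
    """Read a 7-column cytosine report into records, preserving file order.

    Zero-coverage positions are retained.  Malformed lines raise
    :class:`FormatError` naming the offending line number.
    """
    path = Path(path)
    records: list[CytosineRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise FormatError(
                    f"{path.name} line {lineno}: expected 7 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context, tri = fields
            try:
                pos, meth, unmeth = int(pos_s), int(meth_s), int(unmeth_s)
            except ValueError as exc:
                raise FormatError(f"{path.name} line {lineno}: {exc}") from exc
            if pos < 1:
                raise FormatError(f"{path.name} line {lineno}: position {pos} < 1")
            if meth < 0 or unmeth < 0:
                raise FormatError(f"{path.name} line {lineno}: negative read count")
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path.name} line {lineno}: bad strand {strand!r}"
                )
            if context not in CONTEXTS:
                raise FormatError(
                    f"{path.name} line {lineno}: unknown context token {context!r}"
                )
            if not _check_context_trinucleotide(context, tri):
                raise FormatError(
                    f"{path.name} line {lineno}: trinucleotide {tri!r} "
                    f"inconsistent with context {context}"
                )
            records.append(
                CytosineRecord(chrom, pos, strand, meth, unmeth, context, tri)
            )
    return records


def records_to_frame(records: Iterable[CytosineRecord]) -> pd.DataFrame:
    """Vectorised view of cytosine records (columns match the record fields)."""
    return pd.DataFrame(
        [
            (r.chrom, r.pos, r.strand, r.count_meth, r.count_unmeth, r.context, r.trinucleotide)
            for r in records
        ],
        columns=[
            "chrom", "pos", "strand", "count_meth", "count_unmeth", "context", "trinucleotide",
        ],
    )


def write_cx_report(records: Iterable[CytosineRecord], path) -> None:
    with Path(path).open("w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.count_meth}\t"
                f"{r.count_unmeth}\t{r.context}\t{r.trinucleotide}\n"
            )


# ---------------------------------------------------------------------------
# Annotations

_GFF_EXT = {".gff", ".gff3"}
_BED_EXT = {".bed"}


def read_annotations(path, kind: str) -> list[AnnotationFeature]:
    """Read gene or TE annotations from GFF3 or BED (detected by extension).

    All features are normalised to 0-based half-open coordinates: a GFF
    start ``s`` becomes ``s - 1``; BED intervals pass through unchanged.
    For TEs the family code is taken from the ``Family=`` GFF attribute or
    the 7th BED column when present.
    """
    if kind not in ("gene", "TE"):
        raise ValueError(f"kind must be 'gene' or 'TE', got {kind!r}")
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _GFF_EXT:
        feats = _read_gff(path, kind)
    elif ext in _BED_EXT:
        feats = _read_bed(path, kind)
    else:
        raise FormatError(f"unknown annotation format for {path.name!r}")
    if not feats:
        logger.warning("no %s features found in %s", kind, path)
    return feats


def _gff_attributes(raw: str) -> dict:
    out = {}
    for chunk in raw.strip().split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_gff(path: Path, kind: str) -> list[AnnotationFeature]:
    feats = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path.name} line {lineno}: GFF needs 9 columns")
            chrom, _src, _ftype, start_s, end_s, _score, strand, _frame, attrs_s = fields[:9]
            start, end = int(start_s) - 1, int(end_s)
            if start >= end:
                raise FormatError(
                    f"{path.name} line {lineno}: empty interval after normalisation"
                )
            attrs = _gff_attributes(attrs_s)
            feats.append(
                AnnotationFeature(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand if strand in "+-" else ".",
                    kind=kind,
                    family=attrs.get("Family", "") if kind == "TE" else "",
                    id=attrs.get("ID", f"{kind}:{chrom}:{start}-{end}"),
                )
            )
    return feats


def _read_bed(path: Path, kind: str) -> list[AnnotationFeature]:
    feats = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path.name} line {lineno}: BED needs >=3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(f"{path.name} line {lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else f"{kind}:{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            family = fields[6] if kind == "TE" and len(fields) > 6 else ""
            feats.append(
                AnnotationFeature(chrom, start, end, strand, kind, family, name)
            )
    return feats


# ---------------------------------------------------------------------------
# TE polymorphisms

def read_te_polymorphisms(path) -> list[TEPolymorphism]:
    """Read a BED-like TE indel table.

    Columns: chrom, start, end, type (insertion/deletion), family,
    comma-separated carrier line names.  Insertions may be points
    (start == end, the insertion site in the reference).
    """
    path = Path(path)
    out = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path.name} line {lineno}: need 6 columns")
            chrom, start_s, end_s, type_, family, lines_s = fields[:6]
            try:
                out.append(
                    TEPolymorphism(
                        chrom=chrom,
                        start=int(start_s),
                        end=int(end_s),
                        type=type_,
                        family=family,
                        lines=frozenset(x for x in lines_s.split(",") if x),
                    )
                )
            except FormatError as exc:
                raise FormatError(f"{path.name} line {lineno}: {exc}") from exc
    return out


def write_te_polymorphisms(tes: Iterable[TEPolymorphism], path) -> None:
    with Path(path).open("w") as fh:
        for t in tes:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.type}\t{t.family}\t"
                f"{','.join(sorted(t.lines))}\n"
            )


# ---------------------------------------------------------------------------
# SNP tables

_TSV_CODES = {
    "R": "reference", "A": "alternate", "N": "missing",
    "0": "reference", "1": "alternate", ".": "missing",
    "reference": "reference", "alternate": "alternate", "missing": "missing",
}


def read_snp_table(path) -> list[SNPRecord]:
    """Read SNP calls from a genotype TSV or a VCF.

    The TSV dialect is ``chrom  pos  <line1>  <line2> ...`` with a header
    line naming the lines; calls are coded R/A/N (or 0/1/.).  For VCFs only
    the GT field is used: homozygous-reference genotypes map to
    ``reference``, any called non-reference genotype to ``alternate``,
    uncalled to ``missing``.
    """
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz", ".bcf"):
        return _read_snp_vcf(path)
    return _read_snp_tsv(path)


def _read_snp_tsv(path: Path) -> list[SNPRecord]:
    records = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").lstrip("#")
        cols = header.split("\t")
        if len(cols) < 3 or cols[0].lower() != "chrom":
            raise FormatError(f"{path.name}: expected header 'chrom\\tpos\\t<lines...>'")
        lines = cols[2:]
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise FormatError(f"{path.name} line {lineno}: column count mismatch")
            try:
                calls = {ln: _TSV_CODES[c] for ln, c in zip(lines, fields[2:])}
            except KeyError as exc:
                raise FormatError(
                    f"{path.name} line {lineno}: unknown call code {exc}"
                ) from exc
            records.append(SNPRecord(fields[0], int(fields[1]), calls))
    return records


def _read_snp_vcf(path: Path) -> list[SNPRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    lines = list(vcf.samples)
    records = []
    for var in vcf:
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=uncalled
        calls = {}
        for ln, g in zip(lines, var.gt_types):
            if g == 0:
                calls[ln] = "reference"
            elif g in (1, 2):
                calls[ln] = "alternate"
            else:
                calls[ln] = "missing"
        records.append(SNPRecord(var.CHROM, var.POS, calls))
    return records


def write_snp_table(snps: Iterable[SNPRecord], path) -> None:
    snps = list(snps)
    lines = sorted({ln for s in snps for ln in s.calls})
    code = {"reference": "R", "alternate": "A", "missing": "N"}
    with Path(path).open("w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(lines) + "\n")
        for s in snps:
            row = "\t".join(code[s.calls.get(ln, "missing")] for ln in lines)
            fh.write(f"{s.chrom}\t{s.pos}\t{row}\n")


# ---------------------------------------------------------------------------
# Tile output

def write_bedgraph(tiles, context: str, path) -> None:
    """Write per-tile weighted methylation for one context as bedGraph.

    Values are percent methylation rounded to 2 decimals.  Tiles with no
    covered cytosine in the context are omitted.  Input must be sorted by
    (chrom, start).
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    tiles = list(tiles)
    keys = [(t.chrom, t.start) for t in tiles]
    if keys != sorted(keys):
        raise ValueError("tiles must be sorted by (chrom, start)")
    with Path(path).open("w") as fh:
        for t in tiles:
            level = t.level(context)
            if level is None:
                continue
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{level * 100:.2f}\n")


def read_bedgraph(path) -> pd.DataFrame:
    """Parse a bedGraph track into a DataFrame (value on the file's scale)."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
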