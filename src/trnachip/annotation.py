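"""tRNA gene annotations and the four-level family hierarchy.

Human tRNA genes carry gtRNAdb-style names of the form
``tRNA-<Isotype>-<Anticodon>-<IsodecoderFamily>-<GeneCopy>`` (for example
``tRNA-iMet-CAT-1-5``). The name encodes a hierarchy: individual gene <
isodecoder family (identical mature sequence) < isoacceptor family (shared
anticodon) < isotype (shared amino acid). This module parses those names,
reads gene tables (BED6 or the UCSC Table Browser dialect), applies the
high-confidence filtering used to arrive at an analysis gene set, derives
fixed windows around gene centres for signal quantification, and partitions
genes at any hierarchy level.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

log = logging.getLogger(__name__)

_NAME_RE = re.compile(
    r"^tRNA-(?P<isotype>[A-Za-z]+)-(?P<anticodon>[ACGTN]{3})"
    r"-(?P<family>[0-9]+)-(?P<copy>[0-9]+)$"
)

#: Patterns used to exclude loci from analysis sets: nuclear-encoded
#: mitochondrial tRNAs, tRNA-like predictions, and genes on unplaced or
#: alternate contigs. Matched with :func:`re.search` against both the gene
#: name and the chromosome name.
DEFAULT_DROP_PATTERNS: tuple[str, ...] = (
    r"^nmt-",
    r"tRNA-like",
    r"^chrUn",
    r"_alt$",
    r"_random$",
)


class GeneNameError(ValueError):
    """Raised when a gene name does not follow the gtRNAdb convention."""


class GeneTableError(ValueError):
    """Raised when a gene table row cannot be parsed."""


class FamilyLevel(IntEnum):
    """Aggregation levels, totally ordered from finest to coarsest."""

    gene = 0
    isodecoder = 1
    isoacceptor = 2
    isotype = 3

    @classmethod
    def coerce(cls, level: "FamilyLevel | str") -> "FamilyLevel":
        if isinstance(level, cls):
            return level
        try:
            return cls[str(level).lower()]
        except KeyError:
            raise ValueError(
                f"unknown family level {level!r}; expected one of "
                f"{[m.name for m in cls]}"
            ) from None


class ParsedName(NamedTuple):
    isotype: str
    anticodon: str
    isodecoder_family: int
    gene_copy: int


def parse_gene_name(name: str) -> ParsedName:
    """Parse a gtRNAdb-style gene name into its four components.

    >>> parse_gene_name("tRNA-iMet-CAT-1-5")
    ParsedName(isotype='iMet', anticodon='CAT', isodecoder_family=1, gene_copy=5)

    Raises :class:`GeneNameError` naming the offending token when the name
    is malformed.
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise GeneNameError(_diagnose_name(name))
    return ParsedName(
        m["isotype"], m["anticodon"], int(m["family"]), int(m["copy"])
    )


def _diagnose_name(name: str) -> str:
    parts = name.split("-")
    if not parts or parts[0] != "tRNA":
        return f"malformed gene name {name!r}: expected 'tRNA-' prefix, got {parts[0]!r}"
    if len(parts) != 5:
        return (
            f"malformed gene name {name!r}: expected 5 dash-separated fields "
            f"(tRNA-Isotype-Anticodon-Family-Copy), got {len(parts)}"
        )
    _, isotype, anticodon, fam, copy = parts
    if not re.fullmatch(r"[A-Za-z]+", isotype):
        return f"malformed gene name {name!r}: bad isotype token {isotype!r}"
    if not re.fullmatch(r"[ACGTN]{3}", anticodon):
        return f"malformed gene name {name!r}: bad anticodon token {anticodon!r}"
    if not fam.isdigit():
        return f"malformed gene name {name!r}: bad isodecoder-family token {fam!r}"
    return f"malformed gene name {name!r}: bad gene-copy token {copy!r}"


def serialize_gene_name(
    isotype: str, anticodon: str, isodecoder_family: int, gene_copy: int
) -> str:
    return f"tRNA-{isotype}-{anticodon}-{isodecoder_family}-{gene_copy}"


@dataclass(frozen=True)
class TRNAGeneRecord:
    """One annotated tRNA gene with its parsed family identity.

    Coordinates are 0-based half-open. ``anticodon`` is the 3-letter DNA
    string as it appears in the name (``NNN`` for undetermined), and
    ``isotype`` the amino-acid label (``Ser``, ``iMet``, ``SeC``, ``Und`` ...).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    isotype: str = field(default="", compare=False)
    anticodon: str = field(default="", compare=False)
    isodecoder_family: int = field(default=0, compare=False)
    gene_copy: int = field(default=0, compare=False)
    high_confidence: bool = True

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        try:
            parsed = parse_gene_name(self.gene_id)
        except GeneNameError:
            # Non-canonical names (nmt-tRNA-..., tRNA-like predictions) are
            # representable so they can be loaded and then filtered out; they
            # carry no parsed hierarchy unless components are supplied.
            parsed = None
        if parsed is not None:
            if not self.isotype:  # derive family identity from the name
                object.__setattr__(self, "isotype", parsed.isotype)
                object.__setattr__(self, "anticodon", parsed.anticodon)
                object.__setattr__(self, "isodecoder_family", parsed.isodecoder_family)
                object.__setattr__(self, "gene_copy", parsed.gene_copy)
            elif parsed != (self.isotype, self.anticodon,
                            self.isodecoder_family, self.gene_copy):
                raise GeneNameError(
                    f"gene_id {self.gene_id!r} does not re-serialize from "
                    f"the supplied components"
                )

    # Group keys at each level, as plain strings suitable for delimited output.
    @property
    def isodecoder_key(self) -> str:
        return f"{self.isotype}-{self.anticodon}-{self.isodecoder_family}"

    @property
    def isoacceptor_key(self) -> str:
        return f"{self.isotype}-{self.anticodon}"

    @property
    def isotype_key(self) -> str:
        return self.isotype

    def group_key(self, level: FamilyLevel | str) -> str:
        level = FamilyLevel.coerce(level)
        if level is FamilyLevel.gene:
            return self.gene_id
        if level is FamilyLevel.isodecoder:
            return self.isodecoder_key
        if level is FamilyLevel.isoacceptor:
            return self.isoacceptor_key
        return self.isotype_key


@dataclass(frozen=True)
class GenomicWindow:
    """A fixed interval (0-based half-open) around a gene centre."""

    chrom: str
    start: int
    end: int
    clipped: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def window_of(
    record: TRNAGeneRecord,
    flank: int = 500,
    chrom_length: int | None = None,
) -> GenomicWindow:
    """Window of ±``flank`` bp around the gene centre (half-open, 1 kb at
    the default flank), clipped at chromosome boundaries.

    Strand is deliberately ignored: ChIP signal is unstranded.
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    centre = (record.start + record.end) // 2
    start, end = centre - flank, centre + flank
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    return GenomicWindow(record.chrom, start, end, clipped)


# ---------------------------------------------------------------------------
# Gene table readers / writers
# ---------------------------------------------------------------------------

def load_gene_table(
    path: str | Path,
    format: str = "bed",
    ucsc_one_based_start: bool = False,
) -> list[TRNAGeneRecord]:
    """Read tRNA gene records from a BED6 file or a UCSC Table Browser dump.

    Parameters
    ----------
    format:
        ``"bed"`` — BED6 (chrom, start, end, name, score, strand), already
        0-based half-open. ``"ucsc_table"`` — tab-separated Table Browser
        output, optionally with a leading ``#`` header line and a leading
        ``bin`` column.
    ucsc_one_based_start:
        UCSC browser *tables* store 0-based starts, which is the assumed
        dialect; set this flag for exports whose starts are 1-based (as in
        browser display coordinates) to have them decremented on read.
    """
    path = Path(path)
    if format not in {"bed", "ucsc_table"}:
        raise ValueError(f"unknown gene table format {format!r}")
    records: list[TRNAGeneRecord] = []
    seen_styles: set[str] = set()
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#") or line.lower().startswith("track "):
                if format == "ucsc_table" and line.startswith("#"):
                    header = line.lstrip("#").split("\t")
                continue
            fields = line.split("\t")
            try:
                if format == "bed":
                    rec = _record_from_bed(fields)
                else:
                    rec = _record_from_ucsc(fields, header, ucsc_one_based_start)
            except (GeneNameError, ValueError, IndexError) as exc:
                raise GeneTableError(f"{path.name}:{lineno}: {exc}") from exc
            seen_styles.add("chr" if rec.chrom.startswith("chr") else "bare")
            records.append(rec)
    if len(seen_styles) > 1:
        log.warning(
            "%s mixes 'chr'-prefixed and bare chromosome names", path.name
        )
    return records


def _record_from_bed(fields: Sequence[str]) -> TRNAGeneRecord:
    if len(fields) < 4:
        raise ValueError(f"BED row needs >=4 columns, got {len(fields)}")
    chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
    strand = fields[5] if len(fields) > 5 and fields[5] in {"+", "-"} else "+"
    return TRNAGeneRecord(gene_id=name, chrom=chrom, start=start, end=end, strand=strand)


def _record_from_ucsc(
    fields: Sequence[str],
    header: Sequence[str] | None,
    one_based_start: bool,
) -> TRNAGeneRecord:
    if header is not None and len(header) == len(fields):
        row = dict(zip(header, fields))
        chrom = row.get("chrom") or row.get("#chrom")
        start = int(row.get("chromStart") or row.get("txStart"))
        end = int(row.get("chromEnd") or row.get("txEnd"))
        name = row.get("name")
        strand = row.get("strand", "+")
    else:
        # No header: tolerate an optional leading integer 'bin' column.
        offset = 0 if fields[0].startswith("chr") or not fields[0].isdigit() else 1
        chrom = fields[offset]
        start, end = int(fields[offset + 1]), int(fields[offset + 2])
        name = fields[offset + 3]
        strand = (
            fields[offset + 5]
            if len(fields) > offset + 5 and fields[offset + 5] in {"+", "-"}
            else "+"
        )
    if one_based_start:
        start -= 1
    if chrom is None or name is None:
        raise ValueError("row lacks chrom/name columns")
    return TRNAGeneRecord(gene_id=name, chrom=chrom, start=start, end=end, strand=strand)


def write_bed6(records: Iterable[TRNAGeneRecord], path: str | Path) -> None:
    """Write records as canonical BED6 (score column = 0)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.gene_id}\t0\t{rec.strand}\n"
            )


def write_family_map(records: Iterable[TRNAGeneRecord], path: str | Path) -> None:
    """Export the gene → family-key mapping as a tab-separated table."""
    with open(path, "w") as fh:
        fh.write("gene_id\tisodecoder_key\tisoacceptor_key\tisotype_key\n")
        for rec in records:
            fh.write(
                f"{rec.gene_id}\t{rec.isodecoder_key}\t{rec.isoacceptor_key}"
                f"\t{rec.isotype_key}\n"
            )


# ---------------------------------------------------------------------------
# Filtering and grouping
# ---------------------------------------------------------------------------

def filter_gene_set(
    records: Sequence[TRNAGeneRecord],
    high_confidence_ids: Iterable[str],
    keep_exceptions: Iterable[str] = (),
    drop_patterns: Iterable[str] = DEFAULT_DROP_PATTERNS,
) -> list[TRNAGeneRecord]:
    """Restrict to the curated high-confidence gene set.

    A record is retained iff its id is in ``high_confidence_ids`` or in
    ``keep_exceptions`` (for genes kept despite curation, e.g. a
    selenocysteine locus), and neither its id nor its chromosome matches any
    of ``drop_patterns``. Counts removed per reason are logged.
    """
    hc = set(high_confidence_ids)
    keep = set(keep_exceptions)
    compiled = [re.compile(p) for p in drop_patterns]
    kept: list[TRNAGeneRecord] = []
    removed: dict[str, int] = {}
    for rec in records:
        reason = None
        for pat in compiled:
            if pat.search(rec.gene_id) or pat.search(rec.chrom):
                reason = f"pattern {pat.pattern!r}"
                break
        if reason is None and rec.gene_id not in hc and rec.gene_id not in keep:
            reason = "not high-confidence"
        if reason is None:
            kept.append(rec)
        else:
            removed[reason] = removed.get(reason, 0) + 1
    for reason, n in sorted(removed.items()):
        log.info("filter_gene_set: removed %d record(s): %s", n, reason)
    log.info("filter_gene_set: retained %d of %d records", len(kept), len(records))
    return kept


def group_by_level(
    records: Sequence[TRNAGeneRecord],
    level: FamilyLevel | str,
) -> dict[str, list[str]]:
    """Partition gene ids by the group key at ``level``.

    At every level the groups are disjoint and jointly cover the input, and
    each finer-level group is contained in exactly one coarser-level group.
    """
    level = FamilyLevel.coerce(level)
    groups: dict[str, list[str]] = {}
    for rec in records:
        groups.setdefault(rec.group_key(level), []).append(rec.gene_id)
    return groups


def sort_by_position(
    records: Sequence[TRNAGeneRecord],
) -> list[TRNAGeneRecord]:
    """Genomic order: chromosomes in natural (numeric-aware) order, then start."""

    def chrom_key(chrom: str) -> tuple:
        body = chrom[3:] if chrom.startswith("chr") else chrom
        return (0, int(body)) if body.isdigit() else (1, body)

    return sorted(records, key=lambda r: (chrom_key(r.chrom), r.start, r.end))
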