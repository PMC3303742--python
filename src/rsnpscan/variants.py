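"""Variants and coordinate systems.

Positions live in one of three systems: absolute (1-based on the
chromosome, or on the uploaded sequence for anonymous input), relative
to the transcription start site (TSS), or relative to the A of the
start codon (ATG). Relative systems follow the promoter convention
with no position 0: +1 is the anchor base itself and -1 the base
immediately 5' of it, so -1 abuts +1. On minus-strand genes relative
positions count in the 3'->5' genomic direction (upstream of a minus
gene has larger genomic coordinates).
"""

from __future__ import annotations

import logging
import os
import re
import tempfile
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

from .errors import (
    CoordinateError,
    ParseError,
    ReferenceMismatchError,
    UsageError,
)
from .motifs import BASE_INDEX

logger = logging.getLogger(__name__)

SYSTEMS = ("absolute", "tss", "atg")


@dataclass(frozen=True)
class RegionSpec:
    """A 1-based inclusive chromosome region (genome-browser convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1:
            raise UsageError(f"region start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise UsageError(f"region end {self.end} < start {self.start}")


@dataclass(frozen=True)
class CoordinateContext:
    """Anchors mapping absolute positions to TSS/ATG-relative ones.

    ``seq_abs_start`` is the absolute position of the first base of the
    working sequence (1 for anonymous uploaded sequences).
    """

    chrom: Optional[str] = None
    seq_abs_start: int = 1
    tss_abs: Optional[int] = None
    atg_abs: Optional[int] = None
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise UsageError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.seq_abs_start < 1:
            raise UsageError("seq_abs_start must be >= 1")

    def anchor(self, system: str) -> int:
        if system == "tss":
            if self.tss_abs is None:
                raise CoordinateError("context has no TSS anchor")
            return self.tss_abs
        if system == "atg":
            if self.atg_abs is None:
                raise CoordinateError("context has no ATG anchor")
            return self.atg_abs
        raise UsageError(f"unknown coordinate system {system!r}")

    def abs_to_index(self, abs_pos: int, seq_len: int) -> int:
        """0-based index of an absolute position in the working sequence."""
        idx = abs_pos - self.seq_abs_start
        if not 0 <= idx < seq_len:
            raise UsageError(
                f"absolute position {abs_pos} outside working sequence "
                f"[{self.seq_abs_start}, {self.seq_abs_start + seq_len - 1}]"
            )
        return idx


@dataclass(frozen=True)
class Variant:
    """A single-nucleotide substitution in absolute coordinates."""

    variant_id: str
    abs_pos: int
    ref_allele: str
    alt_allele: str
    source: str = "notation"  # notation | table | vcf | diff

    def __post_init__(self):
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if allele not in BASE_INDEX:
                raise UsageError(
                    f"{self.variant_id}: {name} allele must be one of A,C,G,T, "
                    f"got {allele!r}"
                )
        if self.ref_allele == self.alt_allele:
            raise UsageError(f"{self.variant_id}: ref and alt alleles are identical")
        if self.abs_pos < 1:
            raise UsageError(f"{self.variant_id}: position must be >= 1")

    def notation(self, context: Optional[CoordinateContext] = None,
                 system: str = "absolute") -> str:
        """Render as AposB in the requested coordinate system."""
        pos = self.abs_pos
        if system != "absolute":
            if context is None:
                raise CoordinateError("relative notation needs a coordinate context")
            pos = convert_coordinate(context, pos, "absolute", system)
        return f"{self.ref_allele}{pos}{self.alt_allele}"


# ---------------------------------------------------------------------------
# Parsing

_REGION_RE = re.compile(r"^\s*([\w.]+)\s*:\s*([\d,]+)\s*-\s*([\d,]+)\s*$")


def parse_region(text: str) -> RegionSpec:
    """Parse a ``chrN:xxx-yyy`` region string (commas in numbers OK)."""
    m = _REGION_RE.match(text)
    if not m:
        raise ParseError(f"malformed region string {text!r}; expected chrN:xxx-yyy")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if end < start:
        raise UsageError(f"region end {end} < start {start} in {text!r}")
    return RegionSpec(chrom, start, end)


_POS_AB_RE = re.compile(r"^\s*([+-]?\d+)\s*([ACGTacgt])\s*>\s*([ACGTacgt])\s*$")
_A_POS_B_RE = re.compile(r"^\s*([ACGTacgt])\s*([+-]?\d+)\s*([ACGTacgt])\s*$")


def parse_variant_notation(
    text: str,
    context: Optional[CoordinateContext] = None,
    system: str = "absolute",
    variant_id: Optional[str] = None,
) -> Variant:
    """Parse the compact notations ``posA>B`` and ``AposB``.

    ``system`` declares the coordinate system of the written position;
    TSS/ATG-relative positions are converted to absolute via the
    context. Position 0 is invalid in relative systems (-1 abuts +1).
    """
    m = _POS_AB_RE.match(text)
    if m:
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
    else:
        m = _A_POS_B_RE.match(text)
        if not m:
            raise ParseError(
                f"malformed variant notation {text!r}; expected posA>B or AposB"
            )
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if system not in SYSTEMS:
        raise UsageError(f"unknown coordinate system {system!r}")
    if system == "absolute":
        abs_pos = pos
    else:
        if context is None:
            raise CoordinateError(f"notation in {system} coordinates needs a context")
        abs_pos = convert_coordinate(context, pos, system, "absolute")
    return Variant(
        variant_id if variant_id is not None else text.strip(),
        abs_pos,
        ref.upper(),
        alt.upper(),
        source="notation",
    )


def convert_coordinate(
    context: CoordinateContext, pos: int, from_system: str, to_system: str
) -> int:
    """Convert a position between absolute and TSS/ATG-relative systems.

    Relative systems skip 0: +1 is the anchor base, -1 the base 5' of
    it. On the minus strand +1 is still the anchor base but +2 lies at
    anchor-1 genomically (downstream of a minus-strand gene means
    decreasing genomic coordinate).
    """
    for s in (from_system, to_system):
        if s not in SYSTEMS:
            raise UsageError(f"unknown coordinate system {s!r}")
    # to absolute
    if from_system == "absolute":
        abs_pos = pos
    else:
        if pos == 0:
            raise CoordinateError(
                f"position 0 does not exist in the {from_system}-relative system"
            )
        a = context.anchor(from_system)
        if context.strand == "+":
            abs_pos = a + pos - 1 if pos > 0 else a + pos
        else:
            abs_pos = a - pos + 1 if pos > 0 else a - pos
    if to_system == "absolute":
        return abs_pos
    a = context.anchor(to_system)
    if context.strand == "+":
        return abs_pos - a + 1 if abs_pos >= a else abs_pos - a
    return a - abs_pos + 1 if abs_pos <= a else a - abs_pos


# ---------------------------------------------------------------------------
# Sequence editing / diffing


def apply_allele(
    sequence: str,
    variant: Variant,
    which: str,
    context: Optional[CoordinateContext] = None,
) -> str:
    """Return the sequence carrying the requested allele of ``variant``.

    ``which='ref'`` verifies the reference allele and returns the input
    unchanged; ``which='alt'`` substitutes the alternate base. The base
    present in the sequence must match the declared reference allele.
    """
    if which not in ("ref", "alt"):
        raise UsageError(f"which must be 'ref' or 'alt', got {which!r}")
    if context is None:
        context = CoordinateContext()
    idx = context.abs_to_index(variant.abs_pos, len(sequence))
    observed = sequence[idx].upper()
    if observed != variant.ref_allele:
        raise ReferenceMismatchError(variant.abs_pos, variant.ref_allele, observed)
    if which == "ref":
        return sequence
    return sequence[:idx] + variant.alt_allele + sequence[idx + 1 :]


def diff_sequences(
    wt: str,
    mut: str,
    context: Optional[CoordinateContext] = None,
    id_prefix: str = "snv",
) -> list[Variant]:
    """Compare two equal-length sequences base by base and emit one
    variant per mismatching position (IDs auto-numbered in order).

    Mismatches involving a non-ACGT character are skipped with a
    warning, since a substitution variant needs two definite alleles.
    """
    if len(wt) != len(mut):
        raise UsageError(
            f"sequences must have equal length to diff ({len(wt)} vs {len(mut)})"
        )
    if context is None:
        context = CoordinateContext()
    variants = []
    n = 0
    for i, (a, b) in enumerate(zip(wt.upper(), mut.upper())):
        if a == b:
            continue
        if a not in BASE_INDEX or b not in BASE_INDEX:
            logger.warning(
                "diff: skipping mismatch at index %d with non-ACGT base (%r vs %r)",
                i, a, b,
            )
            continue
        n += 1
        variants.append(
            Variant(f"{id_prefix}{n}", context.seq_abs_start + i, a, b, source="diff")
        )
    return variants


# ---------------------------------------------------------------------------
# Tabular input

RsLookup = Mapping[str, tuple[int, str, str]]


def load_rs_lookup(source: Union[str, os.PathLike, IO[str]]) -> dict[str, tuple[int, str, str]]:
    """Load a user-supplied rs-ID lookup table (TSV: id, pos, ref, alt)."""
    close = False
    if isinstance(source, (str, os.PathLike)):
        source = open(source)
        close = True
    try:
        table: dict[str, tuple[int, str, str]] = {}
        for raw in source:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"rs lookup row needs 4 columns: {line!r}")
            table[fields[0]] = (int(fields[1]), fields[2].upper(), fields[3].upper())
        return table
    finally:
        if close:
            source.close()


def _load_tsv_variants(handle: IO[str], rs_lookup: Optional[RsLookup]) -> list[Variant]:
    variants = []
    for lineno, raw in enumerate(handle, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) == 1 and rs_lookup is not None:
            entry = rs_lookup.get(fields[0])
            if entry is None:
                logger.warning("variant table line %d: unknown rs ID %s, skipped",
                               lineno, fields[0])
                continue
            pos, ref, alt = entry
            fields = [fields[0], str(pos), ref, alt]
        if len(fields) < 4:
            logger.warning("variant table line %d: expected 4 columns (id pos ref alt), "
                           "got %d; skipped", lineno, len(fields))
            continue
        vid, pos_s, ref, alt = fields[:4]
        ref, alt = ref.upper(), alt.upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in BASE_INDEX or alt not in BASE_INDEX:
            logger.warning("variant table line %d: %s is not a single-nucleotide "
                           "substitution, skipped", lineno, vid)
            continue
        variants.append(Variant(vid, int(pos_s), ref, alt, source="table"))
    return variants


def _load_vcf_variants(source: Union[str, os.PathLike, IO[str]]) -> list[Variant]:
    import pysam

    tmp_path = None
    if not isinstance(source, (str, os.PathLike)):
        # pysam needs a path; spool stream contents to a temporary file
        with tempfile.NamedTemporaryFile(
            "w", suffix=".vcf", delete=False
        ) as tmp:
            tmp.write(source.read())
            tmp_path = tmp.name
        path = tmp_path
    else:
        path = os.fspath(source)
    variants = []
    try:
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                vid = rec.id if rec.id else f"{rec.chrom}:{rec.pos}"
                ref = (rec.ref or "").upper()
                if len(ref) != 1 or ref not in BASE_INDEX:
                    logger.warning("VCF record %s: REF %r is not a single nucleotide, "
                                   "skipped", vid, rec.ref)
                    continue
                for alt in rec.alts or ():
                    alt = alt.upper()
                    if len(alt) != 1 or alt not in BASE_INDEX:
                        logger.warning("VCF record %s: ALT %r is not a single "
                                       "nucleotide, skipped", vid, alt)
                        continue
                    variants.append(Variant(vid, rec.pos, ref, alt, source="vcf"))
    finally:
        if tmp_path is not None:
            os.unlink(tmp_path)
    return variants


def load_variant_table(
    source: Union[str, os.PathLike, IO[str]],
    format: str = "tsv",
    rs_lookup: Optional[RsLookup] = None,
) -> list[Variant]:
    """Load variants from a TSV table (columns id, pos, ref, alt) or a
    minimal VCF (SNV records only).

    Indels and multi-nucleotide records are skipped with a warning;
    multi-allelic VCF records expand to one variant per alternate
    allele. A TSV row holding only an identifier is resolved through
    ``rs_lookup`` when provided, and skipped with a warning otherwise.
    """
    if format == "vcf":
        return _load_vcf_variants(source)
    if format != "tsv":
        raise UsageError(f"unknown variant table format {format!r}")
    if isinstance(source, (str, os.PathLike)):
        with open(source) as handle:
            return _load_tsv_variants(handle, rs_lookup)
    return _load_tsv_variants(source, rs_lookup)
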