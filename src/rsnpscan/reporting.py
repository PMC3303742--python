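"""Filtering, sorting, annotation and export of hit pairs.

Score filtering uses either-hit semantics: a pair is kept when the
score of *either* of its two hits passes the threshold, so a strong
site deleted by a variant is never filtered away just because the
mutant allele scores poorly. The threshold can be given as a raw score
or as a per-model percentile level of the background score
distribution, which makes cutoffs comparable across models with
different score ranges. All active filters compose conjunctively.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

from .errors import ParseError, UsageError
from .hitpairs import HitPair
from .motifs import ScorePercentiles, percentile_to_threshold
from .scanner import Hit
from .variants import CoordinateContext, Variant, convert_coordinate

SORT_KEYS = ("position", "score", "score_change", "factor_name", "model_id")

TEXT_COLUMNS = [
    "variant_id", "notation", "wt_score", "mut_score", "score_change",
    "model_id", "factor_name", "strand", "chrom", "start", "end",
    "conserved", "significant",
]
ALIGNMENT_COLUMNS = TEXT_COLUMNS + ["wt_site", "mut_site"]


@dataclass(frozen=True)
class FilterSpec:
    """Display/filter settings for a result set.

    At most one of ``min_hit_score`` and ``percentile_level`` may be
    set; both express the either-hit score cutoff.
    """

    min_hit_score: Optional[float] = None
    percentile_level: Optional[float] = None
    min_score_change: Optional[float] = None
    factor_pattern: Optional[str] = None
    best_per_variant: bool = False
    sort_key: str = "position"

    def __post_init__(self):
        if self.min_hit_score is not None and self.percentile_level is not None:
            raise UsageError(
                "set at most one of min_hit_score and percentile_level"
            )
        if self.percentile_level is not None and not 0 <= self.percentile_level <= 1:
            raise UsageError("percentile_level must be in [0, 1]")
        if self.sort_key not in SORT_KEYS:
            raise UsageError(f"unknown sort key {self.sort_key!r}; use one of {SORT_KEYS}")


@dataclass(frozen=True)
class ConservedRegions:
    """Evolutionarily conserved intervals, 0-based half-open (BED-style)."""

    intervals: tuple[tuple[str, int, int], ...]

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        intervals = tuple(sorted((str(c), int(s), int(e)) for c, s, e in intervals))
        for chrom, start, end in intervals:
            if start >= end:
                raise UsageError(f"empty/inverted interval {chrom}:{start}-{end}")
        object.__setattr__(self, "intervals", intervals)

    @classmethod
    def from_bed(cls, source: Union[str, TextIO]) -> "ConservedRegions":
        if isinstance(source, str):
            source = io.StringIO(source)
        intervals = []
        for raw in source:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"BED line needs >= 3 fields: {line!r}")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(intervals)

    def overlaps(self, chrom: Optional[str], start_1based: int, end_1based: int) -> bool:
        """Does the 1-based inclusive span overlap any interval by >= 1 base?"""
        s0, e0 = start_1based - 1, end_1based  # to 0-based half-open
        for c, s, e in self.intervals:
            if chrom is not None and c != chrom:
                continue
            if s0 < e and s < e0:
                return True
        return False


# ---------------------------------------------------------------------------
# Filtering / sorting


def filter_pairs(
    pairs: Sequence[HitPair],
    spec: FilterSpec,
    percentiles: Optional[Mapping[str, ScorePercentiles]] = None,
) -> list[HitPair]:
    """Apply the active filters (conjunctively) to a list of hit pairs."""
    thresholds: dict[str, float] = {}
    if spec.percentile_level is not None:
        if percentiles is None:
            raise UsageError("percentile filtering needs calibration data")
        for pair in pairs:
            mid = pair.model_id
            if mid not in thresholds:
                if mid not in percentiles:
                    raise UsageError(f"no calibration data for model {mid}")
                thresholds[mid] = percentile_to_threshold(
                    percentiles[mid], spec.percentile_level
                )
    kept = []
    pattern = spec.factor_pattern.lower() if spec.factor_pattern else None
    for pair in pairs:
        if spec.min_hit_score is not None and pair.max_hit_score < spec.min_hit_score:
            continue
        if spec.percentile_level is not None and (
            pair.max_hit_score < thresholds[pair.model_id]
        ):
            continue
        if spec.min_score_change is not None and pair.score_change < spec.min_score_change:
            continue
        if pattern is not None and pattern not in pair.factor_name.lower():
            continue
        kept.append(pair)
    return kept


def best_per_variant(pairs: Sequence[HitPair]) -> list[HitPair]:
    """Keep only the best pair (highest score change) for each variant.

    Ties go to the pair with the higher maximum hit score, then to the
    lexicographically smaller model_id. Output preserves the order in
    which variants first appear in the input.
    """
    best: dict[str, HitPair] = {}
    order: list[str] = []
    for pair in pairs:
        vid = pair.variant.variant_id
        if vid not in best:
            best[vid] = pair
            order.append(vid)
            continue
        cur = best[vid]
        # maximize (score_change, max_hit_score); minimize model_id on full tie
        if (pair.score_change, pair.max_hit_score) > (cur.score_change, cur.max_hit_score) or (
            (pair.score_change, pair.max_hit_score) == (cur.score_change, cur.max_hit_score)
            and pair.model_id < cur.model_id
        ):
            best[vid] = pair
    return [best[v] for v in order]


def sort_pairs(pairs: Sequence[HitPair], key: str = "position") -> list[HitPair]:
    """Stable sort: magnitudes (score, score change) descending,
    positions and names ascending."""
    if key == "position":
        return sorted(pairs, key=lambda p: p.abs_start)
    if key == "score":
        return sorted(pairs, key=lambda p: -p.max_hit_score)
    if key == "score_change":
        return sorted(pairs, key=lambda p: -p.score_change)
    if key == "factor_name":
        return sorted(pairs, key=lambda p: p.factor_name.lower())
    if key == "model_id":
        return sorted(pairs, key=lambda p: p.model_id)
    raise UsageError(f"unknown sort key {key!r}; use one of {SORT_KEYS}")


def annotate_conserved(
    pairs: Sequence[HitPair],
    regions: Optional[ConservedRegions],
    context: Optional[CoordinateContext] = None,
) -> list[HitPair]:
    """Flag each pair by whether its site span lies in a conserved region."""
    chrom = context.chrom if context is not None else None
    out = []
    for pair in pairs:
        flag = bool(regions) and regions.overlaps(chrom, pair.abs_start, pair.abs_end)
        out.append(replace(pair, conserved=flag))
    return out


# ---------------------------------------------------------------------------
# Export


def _fmt_score(score: Optional[float]) -> str:
    return "-" if score is None else f"{score:.6g}"


def _pair_row(pair: HitPair, context: Optional[CoordinateContext],
              coordinate_system: str) -> dict[str, str]:
    chrom = context.chrom if context is not None else None
    start, end = pair.abs_start, pair.abs_end
    if coordinate_system != "absolute":
        if context is None:
            raise UsageError("relative coordinate display needs a context")
        start = convert_coordinate(context, start, "absolute", coordinate_system)
        end = convert_coordinate(context, end, "absolute", coordinate_system)
        if context.strand == "-":
            start, end = min(start, end), max(start, end)
    return {
        "variant_id": pair.variant.variant_id,
        "notation": pair.variant.notation(context, coordinate_system),
        "wt_score": _fmt_score(pair.wt_hit.score if pair.wt_hit else None),
        "mut_score": _fmt_score(pair.mut_hit.score if pair.mut_hit else None),
        "score_change": f"{pair.score_change:.6g}",
        "model_id": pair.model_id,
        "factor_name": pair.factor_name,
        "strand": pair.strand,
        "chrom": chrom if chrom is not None else ".",
        "start": str(start),
        "end": str(end),
        "conserved": {True: "yes", False: "no", None: "."}[pair.conserved],
        "significant": "yes" if pair.significant else "no",
        "wt_site": pair.wt_hit.site_seq if pair.wt_hit else "-",
        "mut_site": pair.mut_hit.site_seq if pair.mut_hit else "-",
    }


def export_pairs(
    pairs: Sequence[HitPair],
    format: str = "text",
    delimiter: str = "\t",
    coordinate_system: str = "absolute",
    context: Optional[CoordinateContext] = None,
    compress: bool = False,
) -> Union[str, bytes]:
    """Serialize hit pairs.

    Formats: ``text`` (one delimited row per pair), ``alignments``
    (text plus the two matched site sequences), ``bed`` (0-based
    half-open, score = score change x 250 capped at 1000, suitable as a
    genome-browser custom track) and ``gff`` (GFF version 2,
    feature ``TFBS_variant``, score = score change). BED and GFF
    require a context carrying absolute coordinates (a chromosome
    name). With ``compress=True`` the result is gzip bytes.
    """
    if format in ("text", "alignments"):
        columns = ALIGNMENT_COLUMNS if format == "alignments" else TEXT_COLUMNS
        lines = ["#" + delimiter.join(columns)]
        for pair in pairs:
            row = _pair_row(pair, context, coordinate_system)
            lines.append(delimiter.join(row[c] for c in columns))
        out = "\n".join(lines) + "\n"
    elif format == "bed":
        if context is None or context.chrom is None:
            raise UsageError("BED export needs a context with absolute coordinates")
        lines = ['track name="rsnpscan" description="TFBS score changes"']
        for pair in pairs:
            score = min(1000, round(pair.score_change * 250))
            lines.append(
                "\t".join([
                    context.chrom,
                    str(pair.abs_start - 1),
                    str(pair.abs_end),
                    f"{pair.factor_name}|{pair.variant.variant_id}",
                    str(score),
                    pair.strand,
                ])
            )
        out = "\n".join(lines) + "\n"
    elif format == "gff":
        if context is None or context.chrom is None:
            raise UsageError("GFF export needs a context with absolute coordinates")
        lines = ["##gff-version 2"]
        for pair in pairs:
            attrs = (
                f'Model "{pair.model_id}"; Factor "{pair.factor_name}"; '
                f'Variant "{pair.variant.variant_id}"; '
                f'Direction "{pair.direction}"'
            )
            lines.append(
                "\t".join([
                    context.chrom, "rsnpscan", "TFBS_variant",
                    str(pair.abs_start), str(pair.abs_end),
                    f"{pair.score_change:.6g}", pair.strand, ".", attrs,
                ])
            )
        out = "\n".join(lines) + "\n"
    else:
        raise UsageError(f"unknown export format {format!r}")
    if compress:
        return gzip.compress(out.encode())
    return out


def parse_text_export(
    text: str, delimiter: str = "\t"
) -> list[dict[str, Union[str, float, int, None]]]:
    """Parse a ``text``/``alignments`` export back into records.

    The round trip is lossless for every field the format carries;
    scores come back as floats (``None`` for an absent hit) and
    coordinates as integers.
    """
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines or not lines[0].startswith("#"):
        raise ParseError("text export must start with a '#'-prefixed header row")
    columns = lines[0][1:].split(delimiter)
    records = []
    for line in lines[1:]:
        fields = line.split(delimiter)
        if len(fields) != len(columns):
            raise ParseError(
                f"row has {len(fields)} fields, header has {len(columns)}"
            )
        rec: dict[str, Union[str, float, int, None]] = dict(zip(columns, fields))
        for col in ("wt_score", "mut_score"):
            rec[col] = None if rec[col] == "-" else float(rec[col])
        rec["score_change"] = float(rec["score_change"])
        rec["start"] = int(rec["start"])
        rec["end"] = int(rec["end"])
        records.append(rec)
    return records
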