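"""End-to-end analysis: scan both alleles of each variant, pair hits,
filter, annotate and export.

Each variant is evaluated independently on the otherwise-wildtype
sequence; combined haplotypes are not modeled. A variant whose declared
reference allele disagrees with the working sequence is skipped with a
warning rather than aborting the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

from .errors import ReferenceMismatchError, UsageError
from .hitpairs import (
    DEFAULT_SIGNIFICANCE_THRESHOLD,
    HitPair,
    pair_hits,
)
from .motifs import ScorePercentiles, ScoringModel
from .reporting import (
    ConservedRegions,
    FilterSpec,
    annotate_conserved,
    best_per_variant,
    export_pairs,
    filter_pairs,
    sort_pairs,
)
from .scanner import scan_around_variant
from .variants import CoordinateContext, Variant

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one analysis run needs, already resolved to objects."""

    models: Sequence[ScoringModel]
    sequence: str
    variants: Sequence[Variant]
    context: CoordinateContext = field(default_factory=CoordinateContext)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    percentiles: Optional[Mapping[str, ScorePercentiles]] = None
    conserved: Optional[ConservedRegions] = None
    significance_threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD
    export_format: str = "text"
    delimiter: str = "\t"
    coordinate_system: str = "absolute"
    compress: bool = False


@dataclass
class RunSummary:
    """Counts mirroring the result-page summary: pairs displayed out of
    the total produced."""

    variants_total: int = 0
    variants_skipped: int = 0
    pairs_total: int = 0
    pairs_displayed: int = 0
    significant_pairs: int = 0
    warnings: list[str] = field(default_factory=list)

    def format(self) -> str:
        return (
            f"variants analyzed: {self.variants_total - self.variants_skipped}"
            f" (of {self.variants_total}; {self.variants_skipped} skipped)\n"
            f"hit pairs displayed: {self.pairs_displayed} out of {self.pairs_total}\n"
            f"significant pairs (score change >= threshold): {self.significant_pairs}\n"
        )


@dataclass
class RunResult:
    pairs: list[HitPair]
    summary: RunSummary
    export: Union[str, bytes]


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full variant-impact analysis described by ``config``.

    For every variant: scan both alleles over the windows covering it,
    pair the resulting hits, then apply conservation annotation,
    filters, optional best-per-variant reduction, sorting and export.
    """
    if not config.models:
        raise UsageError("pipeline stage 'models': empty model library")
    summary = RunSummary(variants_total=len(config.variants))
    all_pairs: list[HitPair] = []
    for variant in config.variants:
        try:
            wt_hits, mut_hits = scan_around_variant(
                config.models, config.sequence, variant, config.context
            )
        except ReferenceMismatchError as exc:
            msg = f"variant {variant.variant_id} skipped: {exc}"
            logger.warning(msg)
            summary.variants_skipped += 1
            summary.warnings.append(msg)
            continue
        all_pairs.extend(
            pair_hits(wt_hits, mut_hits, variant, config.significance_threshold)
        )
    summary.pairs_total = len(all_pairs)

    pairs = annotate_conserved(all_pairs, config.conserved, config.context)
    pairs = filter_pairs(pairs, config.filter_spec, config.percentiles)
    if config.filter_spec.best_per_variant:
        pairs = best_per_variant(pairs)
    pairs = sort_pairs(pairs, config.filter_spec.sort_key)

    summary.pairs_displayed = len(pairs)
    summary.significant_pairs = sum(p.significant for p in pairs)
    export = export_pairs(
        pairs,
        format=config.export_format,
        delimiter=config.delimiter,
        coordinate_system=config.coordinate_system,
        context=config.context,
        compress=config.compress,
    )
    return RunResult(pairs=pairs, summary=summary, export=export)
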