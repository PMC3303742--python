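"""Hit pairing and the score-change statistic.

After scanning both alleles of a variant, predicted sites are matched
on (model, strand, start). Sites present on both alleles with the same
score are unaffected by the variant and dropped. Matched sites with
different scores form a *hit pair* whose score change is the absolute
score difference. A site present on only one allele forms a singleton
pair: the missing allele's window scored at or below the hit threshold,
so its score is unknown and treated as 0, making the score change equal
to the known hit's score — a lower-bound estimate of the true impact.
This rule applies even when the sub-threshold score is numerically
computable: a negative score only says the window is not a credible
site, not how implausible it is.

A score change of at least 2 (with base-10 log-odds scores) marks the
site as 100 times more or less likely under one allele than the other;
such pairs are flagged significant. This is a prioritization aid, not a
statistical significance test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .errors import InternalConsistencyError, UsageError
from .scanner import Hit
from .variants import Variant

DEFAULT_SIGNIFICANCE_THRESHOLD = 2.0


@dataclass(frozen=True)
class HitPair:
    """Matched wildtype/mutant predictions for one variant and model.

    Either hit may be absent (``None``) but never both. ``direction``
    is ``gain`` when the mutant allele scores higher (or creates the
    site) and ``loss`` when it scores lower (or deletes it). A site
    whose start position moves appears as one loss pair plus one gain
    pair; exporters may group these as a shift.
    """

    variant: Variant
    wt_hit: Optional[Hit]
    mut_hit: Optional[Hit]
    score_change: float
    direction: str  # gain | loss
    significant: bool
    conserved: Optional[bool] = None

    def __post_init__(self):
        if self.wt_hit is None and self.mut_hit is None:
            raise InternalConsistencyError("hit pair with both hits absent")
        if self.score_change < 0:
            raise InternalConsistencyError("score change must be >= 0")
        if self.wt_hit is not None and self.mut_hit is not None:
            if self.wt_hit.key != self.mut_hit.key:
                raise InternalConsistencyError(
                    f"paired hits disagree on key: {self.wt_hit.key} vs {self.mut_hit.key}"
                )

    @property
    def model_id(self) -> str:
        return (self.wt_hit or self.mut_hit).model_id

    @property
    def factor_name(self) -> str:
        return (self.wt_hit or self.mut_hit).factor_name

    @property
    def strand(self) -> str:
        return (self.wt_hit or self.mut_hit).strand

    @property
    def abs_start(self) -> int:
        return (self.wt_hit or self.mut_hit).abs_start

    @property
    def abs_end(self) -> int:
        return (self.wt_hit or self.mut_hit).abs_end

    @property
    def max_hit_score(self) -> float:
        return max(h.score for h in (self.wt_hit, self.mut_hit) if h is not None)


def _index_hits(hits: Sequence[Hit], which: str) -> dict[tuple, Hit]:
    index: dict[tuple, Hit] = {}
    for hit in hits:
        if hit.key in index:
            raise InternalConsistencyError(
                f"duplicate {which} hit for key {hit.key}"
            )
        index[hit.key] = hit
    return index


def pair_hits(
    wt_hits: Sequence[Hit],
    mut_hits: Sequence[Hit],
    variant: Variant,
    significance_threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD,
) -> list[HitPair]:
    """Match the two alleles' hits into pairs and compute score changes.

    Hits are matched on (model_id, strand, abs_start); a single-
    nucleotide substitution preserves length, so unmoved sites share
    coordinates across alleles. Identical-score matches are dropped as
    unaffected. Output is sorted by (abs_start, model_id, strand).
    """
    wt_index = _index_hits(wt_hits, "wildtype")
    mut_index = _index_hits(mut_hits, "mutant")
    pairs: list[HitPair] = []
    for key in sorted(set(wt_index) | set(mut_index),
                      key=lambda k: (k[2], k[0], k[1])):
        wt = wt_index.get(key)
        mut = mut_index.get(key)
        if wt is not None and mut is not None:
            if wt.score == mut.score:
                continue  # unaffected by the variant
            change = abs(wt.score - mut.score)
            direction = "gain" if mut.score > wt.score else "loss"
        elif wt is not None:
            change = wt.score  # mutant score unknown, assumed 0
            direction = "loss"
        else:
            change = mut.score
            direction = "gain"
        pairs.append(
            HitPair(
                variant, wt, mut, change, direction,
                significant=change >= significance_threshold,
            )
        )
    return pairs


def flag_significant(
    pair: HitPair, threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD
) -> bool:
    """True iff the pair's score change reaches ``threshold`` (inclusive),
    regardless of direction."""
    if threshold < 0:
        raise UsageError(f"significance threshold must be >= 0, got {threshold}")
    return pair.score_change >= threshold


def with_significance(pairs: Sequence[HitPair], threshold: float) -> list[HitPair]:
    """Re-flag pairs under a different significance threshold."""
    return [replace(p, significant=flag_significant(p, threshold)) for p in pairs]
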