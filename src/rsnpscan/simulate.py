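"""Synthetic study generator with analytically known ground truth.

Generates motif libraries (as site alignments), a background sequence
with planted consensus binding sites, and two classes of variants:

* *disrupting* SNVs placed inside planted sites at the most
  informative model column, substituting the base with the lowest
  log-odds there — the change maximizing the predicted impact;
* *neutral* SNVs placed at least one model-width away from every
  planted site, so they cannot touch a planted site's windows.

For every variant the generator emits truth records computed by a
deliberately naive per-window reference scorer (plain Python loops
over the model's log-odds entries), together with the pairing rule
applied in closed form: when both allele windows are hits the expected
score change is exactly |logodds[k][alt] - logodds[k][ref]| at the
variant's column; when one window drops below the hit threshold the
expected change equals the surviving hit's score. Planted sites land
on either strand with probability 1/2 to exercise strand handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import GenerationError, UsageError
from .motifs import (
    BASES,
    Background,
    ScoringModel,
    SiteAlignment,
    build_scoring_model,
    counts_from_alignment,
    reverse_complement,
)
from .variants import Variant


@dataclass(frozen=True)
class TruthRecord:
    """Expected pairing outcome for one (variant, model, strand, window)."""

    variant_id: str
    model_id: str
    strand: str
    window_start: int  # 1-based absolute start of the window
    expected_change: float
    expected_direction: str  # gain | loss | none
    wt_score: float
    mut_score: float


@dataclass(frozen=True)
class PlantedSite:
    model_id: str
    strand: str
    abs_start: int  # 1-based
    abs_end: int


@dataclass
class SimulatedStudy:
    """A self-contained fixture: sequence, variants and expected results."""

    sequence: str
    variants: list[Variant]
    truth: list[TruthRecord]
    planted: list[PlantedSite]
    models: list[ScoringModel]
    library: list[SiteAlignment]
    background: Background
    disrupting_ids: list[str]
    neutral_ids: list[str]

    @property
    def fasta_text(self) -> str:
        lines = [">sim_region synthetic study sequence"]
        for i in range(0, len(self.sequence), 70):
            lines.append(self.sequence[i : i + 70])
        return "\n".join(lines) + "\n"

    @property
    def variant_tsv(self) -> str:
        lines = ["#id\tpos\tref\talt"]
        for v in self.variants:
            lines.append(f"{v.variant_id}\t{v.abs_pos}\t{v.ref_allele}\t{v.alt_allele}")
        return "\n".join(lines) + "\n"

    @property
    def truth_tsv(self) -> str:
        lines = ["#variant_id\tmodel_id\tstrand\twindow_start\texpected_change"
                 "\texpected_direction\twt_score\tmut_score"]
        for t in self.truth:
            lines.append(
                f"{t.variant_id}\t{t.model_id}\t{t.strand}\t{t.window_start}"
                f"\t{t.expected_change!r}\t{t.expected_direction}"
                f"\t{t.wt_score!r}\t{t.mut_score!r}"
            )
        return "\n".join(lines) + "\n"

    def expected_best_change(self, variant_id: str) -> float:
        changes = [t.expected_change for t in self.truth
                   if t.variant_id == variant_id and t.expected_direction != "none"]
        return max(changes, default=0.0)


def simulate_library(
    n_models: int,
    width_range: tuple[int, int] = (8, 12),
    information_content: float = 0.9,
    seed: int = 0,
    n_sites: int = 50,
) -> list[SiteAlignment]:
    """Generate alignments of known sites for ``n_models`` synthetic factors.

    Each model draws a random consensus; every site base matches the
    consensus with probability ``0.25 + 0.75 * information_content``
    (so 1.0 gives monomorphic columns and 0.0 random sequence), which
    controls how sharply the resulting log-odds matrices discriminate.
    """
    if n_models < 1:
        raise UsageError("n_models must be >= 1")
    if not 0.0 <= information_content <= 1.0:
        raise UsageError("information_content must be in [0, 1]")
    lo, hi = width_range
    if lo < 4 or hi < lo:
        raise UsageError(f"invalid width range {width_range}")
    rng = np.random.default_rng(seed)
    p_match = 0.25 + 0.75 * information_content
    library = []
    for m in range(n_models):
        width = int(rng.integers(lo, hi + 1))
        consensus = rng.integers(0, 4, size=width)
        sites = []
        for _ in range(n_sites):
            bases = consensus.copy()
            mutate = rng.random(width) >= p_match
            random_bases = rng.integers(0, 4, size=width)
            bases[mutate] = random_bases[mutate]
            sites.append("".join(BASES[b] for b in bases))
        library.append(
            SiteAlignment(f"SIM{m + 1:03d}", f"synTF{m + 1}", sites)
        )
    return library


def _reference_score(model: ScoringModel, window: str, strand: str) -> Optional[float]:
    """Naive per-column scorer used only to produce truth values."""
    if strand == "-":
        window = reverse_complement(window)
    total = 0.0
    for j, base in enumerate(window):
        if base not in BASES:
            return None
        total += float(model.logodds[j][BASES.index(base)])
    return total


def _truth_for_variant(
    variant: Variant,
    sequence: str,
    models: Sequence[ScoringModel],
) -> list[TruthRecord]:
    """Expected pairing outcome for every window overlapping the variant."""
    idx = variant.abs_pos - 1
    mut_seq = sequence[:idx] + variant.alt_allele + sequence[idx + 1 :]
    records = []
    for model in models:
        w = model.width
        for start in range(max(0, idx - w + 1), min(len(sequence) - w, idx) + 1):
            wt_window = sequence[start : start + w]
            mut_window = mut_seq[start : start + w]
            for strand in "+-":
                wt_s = _reference_score(model, wt_window, strand)
                mut_s = _reference_score(model, mut_window, strand)
                if wt_s is None or mut_s is None:
                    continue
                wt_hit = wt_s > model.hit_threshold
                mut_hit = mut_s > model.hit_threshold
                if not wt_hit and not mut_hit:
                    continue
                if wt_hit and mut_hit:
                    if wt_s == mut_s:
                        change, direction = 0.0, "none"
                    else:
                        change = abs(wt_s - mut_s)
                        direction = "gain" if mut_s > wt_s else "loss"
                elif wt_hit:
                    change, direction = wt_s, "loss"
                else:
                    change, direction = mut_s, "gain"
                records.append(
                    TruthRecord(
                        variant.variant_id, model.model_id, strand,
                        start + 1, change, direction, wt_s, mut_s,
                    )
                )
    return records


def simulate_study(
    seq_length: int,
    library: Sequence[SiteAlignment],
    n_planted_sites: int,
    n_disrupting_snvs: int,
    n_neutral_snvs: int,
    seed: int = 0,
    pseudocount: float = 1.0,
    background: Optional[Background] = None,
    log_base: float = 10.0,
) -> SimulatedStudy:
    """Plant consensus sites in a background sequence and place variants.

    Planted sites are separated from each other and from every neutral
    SNV by at least the widest model width, so each variant's truth
    involves only the site it targets (or none). Disrupting SNVs hit
    the most informative column of their site with the worst-scoring
    alternate base. Fully reproducible for a fixed seed.
    """
    if background is None:
        background = Background.uniform()
    if n_disrupting_snvs > n_planted_sites:
        raise GenerationError(
            f"cannot place {n_disrupting_snvs} disrupting SNVs in "
            f"{n_planted_sites} planted sites (one per site)"
        )
    if not library:
        raise UsageError("simulate_study needs a non-empty library")
    rng = np.random.default_rng(seed)
    models = [
        build_scoring_model(counts_from_alignment(aln), pseudocount, background, log_base)
        for aln in library
    ]
    by_id = {m.model_id: m for m in models}
    max_width = max(m.width for m in models)

    # background sequence
    seq_codes = rng.choice(4, size=seq_length, p=background.probs)

    # non-overlapping placements with a max_width buffer between sites
    occupied: list[tuple[int, int]] = []  # 0-based inclusive, buffered
    planted: list[PlantedSite] = []
    site_models = [models[int(rng.integers(0, len(models)))] for _ in range(n_planted_sites)]
    for model in site_models:
        w = model.width
        placed = False
        for _ in range(2000):
            start = int(rng.integers(max_width, seq_length - w - max_width))
            lo, hi = start - max_width, start + w - 1 + max_width
            if all(hi < a or lo > b for a, b in occupied):
                occupied.append((lo, hi))
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not pack {n_planted_sites} sites of width <= {max_width} "
                f"into {seq_length} bp; increase seq_length"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        consensus = model.consensus()
        site_seq = consensus if strand == "+" else reverse_complement(consensus)
        for k, base in enumerate(site_seq):
            seq_codes[start + k] = BASES.index(base)
        planted.append(PlantedSite(model.model_id, strand, start + 1, start + w))

    sequence = "".join(BASES[b] for b in seq_codes)

    # disrupting SNVs: one per chosen planted site, at the most
    # informative column, replacing with the worst-scoring base
    variants: list[Variant] = []
    disrupting_ids: list[str] = []
    chosen = rng.permutation(n_planted_sites)[:n_disrupting_snvs]
    for n, site_idx in enumerate(sorted(chosen), 1):
        site = planted[site_idx]
        model = by_id[site.model_id]
        spread = model.logodds.max(axis=1) - model.logodds.min(axis=1)
        k = int(spread.argmax())  # most informative model column
        worst = int(model.logodds[k].argmin())
        if site.strand == "+":
            g = site.abs_start - 1 + k
            alt = BASES[worst]
        else:
            g = site.abs_end - 1 - k
            alt = reverse_complement(BASES[worst])
        ref = sequence[g]
        if ref == alt:  # consensus is the worst base only in degenerate models
            alt = next(b for b in BASES if b != ref)
        vid = f"dis{n:03d}"
        variants.append(Variant(vid, g + 1, ref, alt, source="table"))
        disrupting_ids.append(vid)

    # neutral SNVs: outside every buffered site interval, pairwise distinct
    neutral_ids: list[str] = []
    taken = {v.abs_pos for v in variants}
    for n in range(1, n_neutral_snvs + 1):
        placed = False
        for _ in range(2000):
            pos0 = int(rng.integers(0, seq_length))
            if pos0 + 1 in taken:
                continue
            if any(a <= pos0 <= b for a, b in occupied):
                continue
            placed = True
            break
        if not placed:
            raise GenerationError("could not place neutral SNVs away from planted sites")
        ref = sequence[pos0]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        vid = f"neu{n:03d}"
        variants.append(Variant(vid, pos0 + 1, ref, alt, source="table"))
        neutral_ids.append(vid)
        taken.add(pos0 + 1)

    variants.sort(key=lambda v: v.abs_pos)
    truth: list[TruthRecord] = []
    for v in variants:
        truth.extend(_truth_for_variant(v, sequence, models))

    return SimulatedStudy(
        sequence=sequence,
        variants=variants,
        truth=truth,
        planted=planted,
        models=models,
        library=list(library),
        background=background,
        disrupting_ids=disrupting_ids,
        neutral_ids=neutral_ids,
    )
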