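"""TFBS scoring models: construction, serialization, scoring, calibration.

A binding-site model is a per-position log-odds matrix (a PSSM) built
from an alignment of known sites or from a JASPAR-style count matrix.
Scoring a window sums the per-column log-odds of its bases against a
background (null) nucleotide distribution; a positive score means the
window is more likely under the motif model than under the background.

With the default ``log_base = 10`` a score difference of 2 between two
windows corresponds to a 100-fold likelihood-ratio change, which is the
convention used to highlight large score changes downstream.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np

from .errors import (
    AlignmentError,
    AlphabetError,
    DegenerateModelError,
    ParseError,
    UsageError,
)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT_INDEX = np.array([3, 2, 1, 0], dtype=np.int8)

_ENCODE_TABLE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3).

    Characters outside {A,C,G,T} (case-insensitive) encode as -1; they
    are legal in sequences but any scoring window containing one is
    skipped rather than scored.
    """
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class SiteAlignment:
    """An ungapped alignment of known binding sites for one factor."""

    model_id: str
    factor_name: str
    sites: tuple[str, ...]

    def __init__(self, model_id: str, factor_name: str, sites: Sequence[str]):
        sites = tuple(s.upper() for s in sites)
        if len(sites) < 2:
            raise AlignmentError(
                f"{model_id}: an alignment needs at least 2 sites, got {len(sites)}"
            )
        width = len(sites[0])
        for s in sites:
            if len(s) != width:
                raise AlignmentError(
                    f"{model_id}: sites have unequal lengths ({width} vs {len(s)})"
                )
            if any(c not in BASE_INDEX for c in s):
                bad = next(c for c in s if c not in BASE_INDEX)
                raise AlphabetError(
                    f"{model_id}: site {s!r} contains non-ACGT character {bad!r}"
                )
        if width < 4:
            raise AlignmentError(f"{model_id}: site width {width} < 4")
        object.__setattr__(self, "model_id", model_id)
        object.__setattr__(self, "factor_name", factor_name)
        object.__setattr__(self, "sites", sites)

    @property
    def width(self) -> int:
        return len(self.sites[0])


@dataclass(frozen=True)
class CountMatrix:
    """Per-position nucleotide observation counts (columns A,C,G,T)."""

    model_id: str
    factor_name: str
    counts: np.ndarray  # shape (width, 4), float

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise UsageError(
                f"{self.model_id}: counts must be width x 4, got shape {counts.shape}"
            )
        if counts.shape[0] < 1:
            raise UsageError(f"{self.model_id}: empty count matrix")
        if not np.all(np.isfinite(counts)) or np.any(counts < 0):
            raise UsageError(f"{self.model_id}: counts must be finite and >= 0")
        if np.any(counts.sum(axis=1) <= 0):
            raise UsageError(f"{self.model_id}: every position needs a positive count sum")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class Background:
    """Null mononucleotide distribution (A,C,G,T)."""

    probs: np.ndarray

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (4,):
            raise UsageError("background needs exactly 4 probabilities (A,C,G,T)")
        if np.any(probs <= 0):
            raise UsageError("background probabilities must all be > 0")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise UsageError(f"background probabilities sum to {probs.sum()}, not 1")
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_sequence(cls, seq: str, pseudocount: float = 1.0) -> "Background":
        """Mononucleotide frequencies of ``seq`` (non-ACGT ignored),
        smoothed so no base has probability 0."""
        codes = encode_sequence(seq)
        counts = np.bincount(codes[codes >= 0], minlength=4).astype(float)
        counts += pseudocount
        return cls(counts / counts.sum())


@dataclass(frozen=True)
class ScoringModel:
    """A log-odds matrix with an identity and a hit threshold.

    ``logodds[j, b]`` is the log (in base ``log_base``) of the odds of
    base ``b`` at column ``j`` under the motif versus the background.
    A window is a *hit* only when its summed score exceeds
    ``hit_threshold`` (default 0: a negative score means the window is
    not considered a real binding site).
    """

    model_id: str
    factor_name: str
    logodds: np.ndarray  # (width, 4)
    log_base: float = 10.0
    hit_threshold: float = 0.0

    def __post_init__(self):
        lo = np.asarray(self.logodds, dtype=float)
        if lo.ndim != 2 or lo.shape[1] != 4:
            raise UsageError(f"{self.model_id}: logodds must be width x 4")
        if lo.shape[0] < 1:
            raise UsageError(f"{self.model_id}: empty log-odds matrix")
        if not np.all(np.isfinite(lo)):
            raise DegenerateModelError(f"{self.model_id}: non-finite log-odds entries")
        if not math.isfinite(self.hit_threshold):
            raise UsageError(f"{self.model_id}: hit_threshold must be finite")
        lo.setflags(write=False)
        object.__setattr__(self, "logodds", lo)

    @property
    def width(self) -> int:
        return self.logodds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.logodds.min(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[b] for b in self.logodds.argmax(axis=1))

    def reverse_complement_logodds(self) -> np.ndarray:
        """Log-odds matrix scoring the reverse-complement strand: scanning
        a window forward with this matrix equals scoring the window's
        reverse complement with the original."""
        return self.logodds[::-1, ::-1]


@dataclass(frozen=True)
class ScorePercentiles:
    """Empirical score quantile function for one model under a background.

    Stores the full set of type-7 quantile knots (level i/(n-1) ->
    i-th order statistic), so linear interpolation between stored
    levels reproduces the type-7 estimator exactly at every level.
    """

    model_id: str
    sample_size: int
    seed: int
    levels: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        levels = np.asarray(self.levels, dtype=float)
        scores = np.asarray(self.scores, dtype=float)
        if self.sample_size < 1000:
            raise UsageError(f"sample_size {self.sample_size} < 1000")
        if levels.shape != scores.shape or levels.ndim != 1:
            raise UsageError("levels and scores must be 1-D arrays of equal length")
        if np.any(np.diff(scores) < 0):
            raise UsageError("quantiles must be non-decreasing in level")
        levels.setflags(write=False)
        scores.setflags(write=False)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "scores", scores)

    @property
    def quantiles(self) -> Mapping[float, float]:
        return dict(zip(self.levels.tolist(), self.scores.tolist()))


# ---------------------------------------------------------------------------
# Operations


def counts_from_alignment(alignment: SiteAlignment) -> CountMatrix:
    """Tally per-column base counts from an alignment of known sites."""
    mat = np.stack([encode_sequence(s) for s in alignment.sites])  # (n, w)
    counts = np.zeros((alignment.width, 4), dtype=float)
    for j in range(alignment.width):
        counts[j] = np.bincount(mat[:, j], minlength=4)
    return CountMatrix(alignment.model_id, alignment.factor_name, counts)


def read_jaspar(source: Union[str, TextIO]) -> list[CountMatrix]:
    """Read JASPAR-format count matrices.

    Accepts a string or text handle holding zero or more records of the
    form ``>ID NAME`` followed by four labeled base rows, with or
    without brackets::

        >MA0004.1 Arnt
        A  [ 4 19  0 ... ]
        C  [16  0 20 ... ]
        ...

    Row order in the file is irrelevant; columns are normalized to
    A,C,G,T order.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    matrices: list[CountMatrix] = []
    record_id = None
    factor = ""
    rows: dict[str, list[float]] = {}

    def flush():
        if record_id is None:
            return
        missing = [b for b in BASES if b not in rows]
        if missing:
            raise ParseError(f"JASPAR record {record_id}: missing base row(s) {missing}")
        lengths = {len(rows[b]) for b in BASES}
        if len(lengths) != 1:
            raise ParseError(
                f"JASPAR record {record_id}: base rows have unequal lengths "
                f"{sorted(len(rows[b]) for b in BASES)}"
            )
        counts = np.array([rows[b] for b in BASES], dtype=float).T
        matrices.append(CountMatrix(record_id, factor, counts))

    for lineno, raw in enumerate(source, 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split(None, 1)
            if not parts:
                raise ParseError(f"line {lineno}: empty JASPAR header")
            record_id = parts[0]
            factor = parts[1].strip() if len(parts) > 1 else record_id
            rows = {}
        else:
            base, _, rest = line.partition(" ") if " " in line else (line[0], "", line[1:])
            base = base.strip().upper()
            if base not in BASE_INDEX or record_id is None:
                raise ParseError(
                    f"line {lineno}: expected a base row (A/C/G/T) "
                    + (f"in record {record_id}" if record_id else "after a '>' header")
                )
            numbers = rest.replace("[", " ").replace("]", " ").split()
            try:
                values = [float(x) for x in numbers]
            except ValueError as exc:
                raise ParseError(f"JASPAR record {record_id}: bad number in {base} row") from exc
            if base in rows:
                raise ParseError(f"JASPAR record {record_id}: duplicate {base} row")
            rows[base] = values
    flush()
    return matrices


def build_scoring_model(
    counts: CountMatrix,
    pseudocount: float = 1.0,
    background: Background | None = None,
    log_base: float = 10.0,
    hit_threshold: float = 0.0,
) -> ScoringModel:
    """Turn a count matrix into a log-odds scoring model.

    The per-column emission probability uses Dirichlet smoothing with
    the pseudocount distributed according to the background::

        p[j][b] = (counts[j][b] + pseudocount * bg[b]) / (rowsum[j] + pseudocount)

    and ``logodds[j][b] = log(p[j][b] / bg[b]) / log(log_base)``.

    With ``pseudocount = 0`` every count must be positive, otherwise the
    matrix would contain -infinity entries.
    """
    if background is None:
        background = Background.uniform()
    if pseudocount < 0:
        raise UsageError(f"pseudocount must be >= 0, got {pseudocount}")
    if log_base <= 0 or log_base == 1:
        raise UsageError(f"log_base must be positive and != 1, got {log_base}")
    c = counts.counts
    if pseudocount == 0 and np.any(c == 0):
        j, b = np.argwhere(c == 0)[0]
        raise DegenerateModelError(
            f"{counts.model_id}: zero count for {BASES[b]} at column {j} "
            "with zero pseudocount would give infinite log-odds"
        )
    bg = background.probs
    p = (c + pseudocount * bg) / (c.sum(axis=1, keepdims=True) + pseudocount)
    logodds = np.log(p / bg) / np.log(log_base)
    return ScoringModel(
        counts.model_id, counts.factor_name, logodds, log_base, hit_threshold
    )


def score_window(model: ScoringModel, window: str) -> float | None:
    """Score one window of exactly the model's width.

    Returns the sum of per-column log-odds, or ``None`` if the window
    contains any non-ACGT character (such windows are skipped, never
    scored as neutral).
    """
    if len(window) != model.width:
        raise UsageError(
            f"window length {len(window)} != model width {model.width}"
        )
    codes = encode_sequence(window)
    if np.any(codes < 0):
        return None
    return float(model.logodds[np.arange(model.width), codes].sum())


def calibrate_percentiles(
    model: ScoringModel,
    background: Background | None = None,
    sample_size: int = 10000,
    seed: int = 0,
) -> ScorePercentiles:
    """Estimate the model's score distribution under the background.

    Draws ``sample_size`` i.i.d. windows from the background and stores
    the sorted scores as an empirical quantile function. Deterministic
    for a fixed seed. Because score distributions differ across models,
    per-model percentile thresholds make hit quality comparable without
    reference to raw score values.
    """
    if background is None:
        background = Background.uniform()
    if sample_size < 1000:
        raise UsageError(f"sample_size must be >= 1000, got {sample_size}")
    rng = np.random.default_rng(seed)
    windows = rng.choice(4, size=(sample_size, model.width), p=background.probs)
    scores = model.logodds[np.arange(model.width), windows].sum(axis=1)
    scores.sort()
    levels = np.arange(sample_size) / (sample_size - 1)
    return ScorePercentiles(model.model_id, sample_size, seed, levels, scores)


def percentile_to_threshold(percentiles: ScorePercentiles, level: float) -> float:
    """Interpolated empirical quantile (type 7) at ``level`` in [0, 1]."""
    if not 0.0 <= level <= 1.0:
        raise UsageError(f"percentile level must be in [0, 1], got {level}")
    return float(np.interp(level, percentiles.levels, percentiles.scores))


# ---------------------------------------------------------------------------
# Serialization (plain TSV, inspectable and diff-able)


def write_models_tsv(models: Iterable[ScoringModel], handle: TextIO) -> None:
    """Write models as TSV blocks: four header lines then width rows of
    4 log-odds values (columns A,C,G,T)."""
    for model in models:
        handle.write(f"#model_id\t{model.model_id}\n")
        handle.write(f"#factor\t{model.factor_name}\n")
        handle.write(f"#log_base\t{model.log_base:g}\n")
        handle.write(f"#threshold\t{model.hit_threshold:g}\n")
        for row in model.logodds:
            handle.write("\t".join(repr(float(v)) for v in row) + "\n")
        handle.write("\n")


def write_percentiles_tsv(
    tables: Iterable[ScorePercentiles], handle: TextIO
) -> None:
    """Write calibration tables as TSV blocks (every quantile knot is
    written, so the round trip is lossless)."""
    for t in tables:
        handle.write(f"#model_id\t{t.model_id}\n")
        handle.write(f"#sample_size\t{t.sample_size}\n")
        handle.write(f"#seed\t{t.seed}\n")
        for level, score in zip(t.levels, t.scores):
            handle.write(f"{float(level)!r}\t{float(score)!r}\n")
        handle.write("\n")


def read_percentiles_tsv(source: Union[str, TextIO]) -> list[ScorePercentiles]:
    """Read calibration tables written by :func:`write_percentiles_tsv`."""
    if isinstance(source, str):
        source = io.StringIO(source)
    tables: list[ScorePercentiles] = []
    header: dict[str, str] = {}
    levels: list[float] = []
    scores: list[float] = []

    def flush():
        if not header and not levels:
            return
        if "model_id" not in header:
            raise ParseError("percentile TSV block lacks a #model_id header")
        tables.append(
            ScorePercentiles(
                header["model_id"],
                int(header.get("sample_size", len(levels))),
                int(header.get("seed", 0)),
                np.array(levels),
                np.array(scores),
            )
        )

    for raw in source:
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            header, levels, scores = {}, [], []
            continue
        if line.startswith("#"):
            if levels:
                flush()
                header, levels, scores = {}, [], []
            key, _, value = line[1:].partition("\t")
            header[key.strip()] = value.strip()
        else:
            try:
                l_s, s_s = line.split("\t")
                levels.append(float(l_s))
                scores.append(float(s_s))
            except ValueError as exc:
                raise ParseError(
                    f"bad percentile row in {header.get('model_id', '?')}: {line!r}"
                ) from exc
    flush()
    return tables


def read_models_tsv(source: Union[str, TextIO]) -> list[ScoringModel]:
    """Read models written by :func:`write_models_tsv`."""
    if isinstance(source, str):
        source = io.StringIO(source)
    models: list[ScoringModel] = []
    header: dict[str, str] = {}
    rows: list[list[float]] = []

    def flush():
        if not header and not rows:
            return
        if "model_id" not in header:
            raise ParseError("model TSV block lacks a #model_id header")
        if not rows:
            raise ParseError(f"model {header['model_id']}: no matrix rows")
        models.append(
            ScoringModel(
                header["model_id"],
                header.get("factor", header["model_id"]),
                np.array(rows, dtype=float),
                float(header.get("log_base", 10.0)),
                float(header.get("threshold", 0.0)),
            )
        )

    for raw in source:
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            header, rows = {}, []
            continue
        if line.startswith("#"):
            if rows:  # new block starting without a blank separator
                flush()
                header, rows = {}, []
            key, _, value = line[1:].partition("\t")
            header[key.strip()] = value.strip()
        else:
            values = line.split("\t")
            if len(values) != 4:
                raise ParseError(
                    f"model {header.get('model_id', '?')}: expected 4 columns, "
                    f"got {len(values)}"
                )
            try:
                rows.append([float(v) for v in values])
            except ValueError as exc:
                raise ParseError(
                    f"model {header.get('model_id', '?')}: bad number in matrix row"
                ) from exc
    flush()
    return models
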