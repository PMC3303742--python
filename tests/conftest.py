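import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rsnpscan as rs

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def uniform_bg():
    return rs.Background.uniform()


def make_model(model_id="m1", factor="TF1", consensus="TATAAT", n_sites=10,
               pseudocount=1.0, log_base=10.0):
    """A strongly informative model: n_sites identical copies of the
    consensus, Dirichlet-smoothed."""
    aln = rs.SiteAlignment(model_id, factor, [consensus] * n_sites)
    return rs.build_scoring_model(rs.counts_from_alignment(aln), pseudocount,
                                  rs.Background.uniform(), log_base)


def uniform_model(width=6, model_id="u1"):
    """All-zero log-odds: every window scores 0."""
    return rs.ScoringModel(model_id, "uniform", np.zeros((width, 4)))


def naive_scan(library, seq, context=None, allele_tag="wt"):
    """Independent double-loop reference scanner: every model, every
    window, both strands, via per-window score_window calls."""
    if context is None:
        context = rs.CoordinateContext()
    hits = []
    for model in library:
        w = model.width
        for i in range(len(seq) - w + 1):
            window = seq[i : i + w].upper()
            for strand in "+-":
                target = rs.reverse_complement(window) if strand == "-" else window
                score = rs.score_window(model, target)
                if score is not None and score > model.hit_threshold:
                    hits.append(rs.Hit(
                        model.model_id, model.factor_name, strand,
                        context.seq_abs_start + i,
                        context.seq_abs_start + i + w - 1,
                        score, target, allele_tag,
                    ))
    hits.sort(key=lambda h: (h.abs_start, h.model_id, h.strand))
    return hits


def assert_hits_equal(got, expected, rel=1e-9):
    """Field-by-field hit comparison; scores compared to floating-point
    tolerance since strand-reversed summation order may differ."""
    assert len(got) == len(expected)
    for a, b in zip(got, expected):
        assert (a.model_id, a.factor_name, a.strand, a.abs_start, a.abs_end,
                a.site_seq, a.allele_tag) == \
               (b.model_id, b.factor_name, b.strand, b.abs_start, b.abs_end,
                b.site_seq, b.allele_tag)
        assert a.score == pytest.approx(b.score, rel=rel, abs=1e-12)


def random_dna(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[b] for b in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def study():
    """The reference simulated study: 10 kb, 10 models, 25 planted
    sites, 25 disrupting + 25 neutral SNVs."""
    library = rs.simulate_library(10, (8, 12), 0.9, seed=5)
    return rs.simulate_study(10000, library, 25, 25, 25, seed=6)


@pytest.fixture(scope="session")
def study_result(study):
    cfg = rs.RunConfig(models=study.models, sequence=study.sequence,
                       variants=study.variants)
    return rs.run_pipeline(cfg)
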