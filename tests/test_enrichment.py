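import math

import numpy as np
import pytest

from mutsig._seq import Motif, count_motif_occurrences
from mutsig.enrichment import (EnrichmentConfig, EnrichmentResult,
                               TrinucleotideEnrichment, compute_enrichment,
                               correct_pvalues, count_window_contexts,
                               fisher_enrichment_test, fisher_greater,
                               min_mutation_load, trims_scan)
from mutsig.io import GenomeSequence, MutationRecord, MutationSet
from mutsig.simulate import SyntheticConfig, generate_genome, spike_sbs


def _result(a, total, ctx_ref, ctx_motif, **kw):
    r = EnrichmentResult(motif="cCg", substitution="C>G", sample_id="pooled",
                         mutations_motif=a, mutations_total=total,
                         context_ref=ctx_ref, context_motif=ctx_motif,
                         enrichment=None)
    if ctx_motif > 0 and total > 0:
        r.enrichment = (a * ctx_ref) / (total * ctx_motif)
    for k, v in kw.items():
        setattr(r, k, v)
    return r


# --------------------------------------------------------- window contexts

def test_window_contexts_hand_enumeration():
    # genome ACCGA, one C>G mutation at the central C, window covers all:
    # C/G occurrences = C,C,G = 3; cCg-or-cGg occurrences = "CCG" once.
    g = GenomeSequence({"chrI": "ACCGA"})
    ms = MutationSet([MutationRecord("s", "chrI", 3, "C", "G")])
    cfg = EnrichmentConfig(motif="cCg", substitution="C>G", window_radius=20)
    assert count_window_contexts(ms, g, cfg) == (3, 1)


def test_window_contexts_no_motif_hits():
    g = GenomeSequence({"chrI": "ATATACATATA"})
    ms = MutationSet([MutationRecord("s", "chrI", 6, "C", "G")])
    cfg = EnrichmentConfig(motif="cCg", substitution="C>G")
    ref, motif = count_window_contexts(ms, g, cfg)
    assert ref == 1 and motif == 0


def test_window_contexts_match_naive_scan(rng):
    """Optimised motif counting equals a per-position naive scan on random
    1 kb windows."""
    motif = Motif("cCg")
    for _ in range(50):
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        naive = 0
        for i in range(998):
            tri = seq[i:i + 3]
            if tri == "CCG" or tri == "CGG":
                naive += 1
        assert count_motif_occurrences(seq, motif) == naive


# --------------------------------------------------------- enrichment ratio

@pytest.mark.parametrize("a,total,cref,cmot,expected", [
    (8, 10, 1000, 100, 8.0),
    (10, 10, 1000, 1000, 1.0),
    (0, 10, 1000, 100, 0.0),
])
def test_enrichment_arithmetic(a, total, cref, cmot, expected):
    r = _result(a, total, cref, cmot)
    assert r.enrichment == pytest.approx(expected)


def test_enrichment_undefined_when_no_motif_context():
    g = GenomeSequence({"chrI": "ATATACATATA"})
    ms = MutationSet([MutationRecord("s", "chrI", 6, "C", "G")])
    cfg = EnrichmentConfig(motif="cCg", substitution="C>G")
    res = compute_enrichment(ms, g, cfg)
    assert res.undefined and res.enrichment is None
    assert min_mutation_load(res) == 0.0


def test_motif_wildcard_and_pyrimidine_matching():
    # G>C at a cGg site is a C>G at cCg after normalization
    g = GenomeSequence({"chrI": "AACGGAA"})
    ms = MutationSet([MutationRecord("s", "chrI", 4, "G", "C")])
    cfg = EnrichmentConfig(motif="cCg", substitution="C>G")
    res = compute_enrichment(ms, g, cfg)
    assert res.mutations_motif == 1 and res.mutations_total == 1


# --------------------------------------------------------- Fisher's test

def _hypergeom_tail_oracle(a, b, c, d):
    """Independent exhaustive enumeration of the one-sided tail via
    log-factorials."""
    n1, n2, k, N = a + b, c + d, a + c, a + b + c + d
    lf = [math.lgamma(i + 1) for i in range(N + 1)]

    def logpmf(x):
        return (lf[n1] - lf[x] - lf[n1 - x]
                + lf[n2] - lf[k - x] - lf[n2 - (k - x)]
                - (lf[N] - lf[k] - lf[N - k]))

    lo, hi = max(0, k - n2), min(n1, k)
    return sum(math.exp(logpmf(x)) for x in range(a, hi + 1)) if a >= lo \
        else 1.0


@pytest.mark.parametrize("table", [
    (3, 1, 10, 90), (5, 5, 50, 50), (0, 4, 2, 8), (12, 0, 1, 30),
])
def test_fisher_matches_enumeration(table):
    got = float(fisher_greater(*table))
    assert got == pytest.approx(_hypergeom_tail_oracle(*table), rel=1e-10)


def test_fisher_matches_scipy_fisher_exact(rng):
    from scipy.stats import fisher_exact

    for _ in range(50):
        a, b, c, d = rng.integers(0, 40, size=4)
        ours = float(fisher_greater(a, b, c, d))
        ref = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


def test_fisher_degenerate_margin_is_one():
    assert float(fisher_greater(0, 0, 5, 10)) == 1.0
    assert float(fisher_greater(0, 5, 0, 0)) == 1.0


def test_fisher_extremes():
    # all mutations in motif, motif rare in context
    assert fisher_enrichment_test(_result(20, 20, 1000, 10)) < 1e-3
    # same motif fraction in both rows, large counts
    assert fisher_enrichment_test(_result(10, 100, 10_000, 1000)) > 0.05


# --------------------------------------------------------- corrections

def test_bonferroni_correction():
    rs = [_result(1, 2, 10, 5, p_value=p) for p in (0.01, 0.5)]
    correct_pvalues(rs, "bonferroni", m=10)
    assert rs[0].corrected_p == pytest.approx(0.10)
    assert rs[1].corrected_p == 1.0


def test_bh_correction_step_up():
    rs = [_result(1, 2, 10, 5, p_value=p) for p in (0.01, 0.02, 0.03)]
    correct_pvalues(rs, "bh")
    assert [r.corrected_p for r in rs] == pytest.approx([0.03, 0.03, 0.03])


def test_bonferroni_family_too_small_errors():
    rs = [_result(1, 2, 10, 5, p_value=0.1) for _ in range(3)]
    with pytest.raises(ValueError):
        correct_pvalues(rs, "bonferroni", m=2)


# --------------------------------------------------------- minimum load

@pytest.mark.parametrize("n,E,expected", [
    (40, 2.0, 20.0), (40, 8.0, 35.0), (40, 1.0, 0.0), (40, 0.5, 0.0),
])
def test_min_load_worked_values(n, E, expected):
    r = _result(n, 100, 10_000, 100)
    r.enrichment = E
    r.corrected_p = 0.01
    assert min_mutation_load(r, alpha=0.05) == pytest.approx(expected)


def test_min_load_zero_when_not_significant():
    r = _result(40, 100, 10_000, 100)
    r.enrichment = 5.0
    r.corrected_p = 0.2
    assert min_mutation_load(r, alpha=0.05) == 0.0


def test_min_load_bounds_and_limit():
    r = _result(40, 100, 10_000, 100)
    r.corrected_p = 1e-9
    for E in (1.0001, 2, 10, 1e6, 1e12):
        r.enrichment = E
        load = min_mutation_load(r)
        assert 0 <= load <= r.mutations_motif
    r.enrichment = 1e12
    assert min_mutation_load(r) == pytest.approx(40.0, rel=1e-9)


# --------------------------------------------------------- scans

def test_trims_scan_planted_motif_ranks_first(small_bundle):
    rows = trims_scan(small_bundle.mutations, small_bundle.genome,
                      [("cCg", "C>G"), ("nCg", "C>G")])
    by_motif = {r.motif: r for r in rows}
    assert by_motif["cCg"].enrichment > by_motif["nCg"].enrichment
    assert by_motif["cCg"].corrected_p < 0.05
    assert by_motif["cCg"].min_load > 0


def test_trims_scan_uniform_catalog_near_one():
    cfg = SyntheticConfig(seed=77, n_chromosomes=2, chrom_length=200_000,
                          n_isolates=4, sbs_per_isolate=500,
                          target_enrichment=1.0, subtelomeric_fraction=0.2,
                          strand_asymmetry=0.5,
                          class_weights={"C>G": 1.0, "C>A": 0.0, "C>T": 0.0,
                                         "T>A": 0.0, "T>C": 0.0, "T>G": 0.0})
    g = generate_genome(cfg)
    ms = spike_sbs(g, cfg)
    assert len(ms) == 2000
    res = trims_scan(ms, g, [("cCg", "C>G")])[0]
    assert 0.85 <= res.enrichment <= 1.18


def test_trims_scan_empty_catalog():
    g = GenomeSequence({"chrI": "ACGTACGTAC"})
    rows = trims_scan(MutationSet([]), g, [("cCg", "C>G")])
    assert rows[0].mutations_total == 0 and rows[0].min_load == 0.0


def test_model_results_interface(small_bundle):
    model = TrinucleotideEnrichment(small_bundle.mutations,
                                    small_bundle.genome,
                                    motifs=["cCg", "nCg"])
    res = model.fit(per_sample=True)
    frame = res.to_frame()
    assert set(frame["sample"]) >= {"pooled"}
    assert len(res.pooled) == 2
    assert "enrichment" in frame.columns
    text = res.summary()
    assert "cCg" in text and "pooled" in text
    # per-sample Bonferroni family is the number of samples for the motif
    samples = [r for r in res if r.sample_id != "pooled" and r.motif == "cCg"]
    for r in samples:
        assert r.corrected_p == pytest.approx(
            min(1.0, r.p_value * len(samples))) or r.corrected_p == 1.0
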