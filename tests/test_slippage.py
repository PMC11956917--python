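import numpy as np
import pytest

from mutsig.io import GenomeSequence, MutationRecord, MutationSet
from mutsig.slippage import (SlippageConfig, classify_deletion,
                             classify_record, detect_templated_insertion,
                             detect_templated_substitution, indel_summary,
                             slippage_calls)


def _g(seq):
    return GenomeSequence({"chrI": seq})


def _rec(pos, ref, alt, sample="s"):
    return MutationRecord(sample, "chrI", pos, ref, alt)


# --------------------------------------------------------- insertions

def test_insertion_copies_downstream_base():
    # ...T C | A G...  inserting A after C duplicates the downstream A
    g = _g("TTTCAGTT")
    call = detect_templated_insertion(_rec(4, "C", "CA"), g)
    assert call.category == "dup_downstream" and call.templated
    assert call.copied_tract == "A"


def test_insertion_nonmatching_base_untemplated():
    g = _g("TTTCAGTT")
    call = detect_templated_insertion(_rec(4, "C", "CG"), g)
    assert call.category == "untemplated" and not call.templated


def test_insertion_upstream_duplication():
    # ...A A | C G... inserting A after the second A copies upstream
    g = _g("TTAACGTT")
    call = detect_templated_insertion(_rec(4, "A", "AA"), g)
    assert call.category == "dup_upstream" and call.templated


def test_downstream_wins_over_upstream():
    # A | A ... both sides match: +1 copying preferred
    g = _g("TTAAATTT")
    call = detect_templated_insertion(_rec(4, "A", "AA"), g)
    assert call.category == "dup_downstream"


def test_left_aligned_homopolymer_insertion_detected():
    # VCF left-aligns an extra G in "TGGGA" to the anchor before the run;
    # the right-shifted placement reveals the duplication.
    g = _g("TTGGGATT")
    call = detect_templated_insertion(_rec(2, "T", "TG"), g)
    assert call.templated


def test_multibase_insertion_requires_whole_tract():
    g = _g("TTCAGCAGTT")
    dup = detect_templated_insertion(_rec(5, "G", "GCAG"), g)
    assert dup.templated and dup.copied_tract == "CAG"
    partial = detect_templated_insertion(_rec(5, "G", "GCAT"), g)
    assert not partial.templated


def test_insertion_at_chromosome_end_flagged():
    g = _g("TTTC")
    call = detect_templated_insertion(_rec(4, "C", "CA"), g)
    assert not call.templated and "flank" in call.note


# --------------------------------------------------------- deletions

def test_deletion_inside_cg_run():
    g = _g("TACCCCAT")
    call = classify_deletion(_rec(2, "AC", "A"), g)
    assert call.category == "run_deletion" and call.copied_tract == "CCCC"


def test_deletion_outside_run_untemplated():
    g = _g("TTAGTT")
    call = classify_deletion(_rec(2, "TA", "T"), g)
    assert call.category == "untemplated"


def test_deletion_spanning_run_end():
    # deleting CC out of a CCC run stays a run deletion
    g = _g("TACCCAT")
    call = classify_deletion(_rec(3, "CCC", "C"), g)
    assert call.category == "run_deletion"


def test_short_run_below_threshold():
    g = _g("TACCAT")
    call = classify_deletion(_rec(2, "AC", "A"), g)
    assert call.category == "untemplated"


# --------------------------------------------------------- DBS / MBS donors

def test_dbs_donor_at_plus_two():
    #        123456789
    g = _g("TATGCGCTT")  # ref "AT"->alt "GC" at pos 2; GC at +2 and +4
    call = detect_templated_substitution(_rec(2, "AT", "GC"), g)
    assert call.templated and call.donor_offset == 2
    assert call.copied_tract == "GC"


def test_dbs_without_donor_untemplated():
    g = _g("TATAAATATT")
    call = detect_templated_substitution(_rec(2, "AT", "GC"), g)
    assert not call.templated


def test_donor_tie_prefers_downstream():
    #       1234567890    donors "GC" at offsets -3 and +3 from pos 5
    g = _g("TGCAAATGCT")
    call = detect_templated_substitution(_rec(5, "AA", "GC"), g)
    assert call.templated
    assert call.donor_offset == 3


def test_donor_search_equals_naive_scan(rng):
    """Donor search equals a naive scan over every offset on 100 random
    cases."""
    cfg = SlippageConfig(donor_window=10)
    bases = np.array(list("ACGT"))
    for _ in range(100):
        seq = "".join(rng.choice(bases, size=60))
        g = _g(seq)
        L = int(rng.integers(2, 5))
        pos = int(rng.integers(15, 40))
        ref = seq[pos - 1 : pos - 1 + L]
        alt = "".join(rng.choice([b for b in "ACGT" if b != c]) for c in ref)
        rec = _rec(pos, ref, alt)
        call = detect_templated_substitution(rec, g, cfg)
        naive = []
        for d in range(-cfg.donor_window, cfg.donor_window + 1):
            if abs(d) < L:
                continue
            s = pos - 1 + d
            if 0 <= s and s + L <= len(seq) and seq[s : s + L] == alt:
                naive.append(d)
        if naive:
            best = min(naive, key=lambda d: (abs(d), 0 if d > 0 else 1))
            assert call.templated and call.donor_offset == best
        else:
            assert not call.templated


# --------------------------------------------------------- summaries

def test_order_invariance(small_bundle):
    ms = small_bundle.mutations.of_class("INS", "DEL", "DBS", "MBS")
    fwd = slippage_calls(ms, small_bundle.genome)
    shuffled = MutationSet(list(ms)[::-1])
    rev = slippage_calls(shuffled, small_bundle.genome)
    key = lambda c: (c.record.chrom, c.record.pos, c.record.ref, c.record.alt)
    assert [(key(c), c.category, c.donor_offset) for c in fwd] == \
        [(key(c), c.category, c.donor_offset) for c in rev]


def test_indel_summary_proportions():
    g = _g("TTTCAGTTACCCCATTTGCGCTA" + "ACGT" * 10)
    recs = [
        _rec(4, "C", "CA", sample="a"),       # templated ins
        _rec(4, "C", "CT", sample="b"),       # untemplated ins
        _rec(8, "TA", "T", sample="a"),       # non-run del? T A -> del A
        _rec(9, "AC", "A", sample="b"),       # del C in CCCC run
        _rec(18, "CG", "GC", sample="a"),     # DBS
    ]
    summary = indel_summary(MutationSet(recs), g)
    assert summary.n_insertions == 2 and summary.n_deletions == 2
    assert summary.insertion_proportion == pytest.approx(0.5)
    assert summary.templated_insertion_fraction == pytest.approx(0.5)
    assert summary.run_deletion_fraction == pytest.approx(0.5)
    assert summary.tract_length_hist[1] == 4
    assert summary.inserted_base_composition == {"A": 1, "T": 1}


def test_planted_templated_fractions_recovered(small_bundle, small_config):
    summary = indel_summary(small_bundle.mutations, small_bundle.genome)
    n_ins = round(small_config.indel_count * small_config.insertion_fraction)
    assert summary.n_insertions == n_ins
    assert summary.n_deletions == small_config.indel_count - n_ins
    assert summary.n_dbs == small_config.dbs_count
    assert summary.n_mbs == small_config.mbs_count
    # planted counts are exact; detection must reach them
    exp_t = round(n_ins * small_config.templated_insertion_fraction) / n_ins
    assert summary.templated_insertion_fraction >= exp_t  # >= planted: chance
    assert summary.templated_mbs_fraction >= \
        round(small_config.mbs_count * small_config.templated_mbs_fraction) \
        / small_config.mbs_count
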