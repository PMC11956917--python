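import pytest

from mutsig._seq import revcomp
from mutsig.io import GenomeSequence, MutationRecord, MutationSet
from mutsig.spectrum import (SubtelomereConfig, classify_location,
                             group_adjacent, mutation_density,
                             mutations_per_isolate, normalize_substitution,
                             spectrum_table, strand_resolved_spectrum,
                             subtelomeric_territory, telomere_distance)


def _genome(length=500_000, name="chrI"):
    # deterministic periodic sequence long enough for distance tests
    unit = "ACGT" * 250
    seq = (unit * (length // len(unit) + 1))[:length]
    return GenomeSequence({name: seq})


def _rec(pos, ref, alt, sample="s1", chrom="chrI"):
    return MutationRecord(sample, chrom, pos, ref, alt)


# ------------------------------------------------------- telomere distance

@pytest.mark.parametrize("pos,expected", [
    (100, 99), (500_000, 0), (250_000, 249_999), (1, 0),
])
def test_telomere_distance(pos, expected):
    g = _genome()
    ref = g["chrI"][pos - 1]
    r = MutationRecord("s", "chrI", pos, ref, "A" if ref != "A" else "C")
    assert telomere_distance(r, g) == expected


def test_telomere_distance_unknown_chromosome():
    with pytest.raises(KeyError):
        telomere_distance(_rec(5, "A", "C", chrom="chrZ"), _genome())


@pytest.mark.parametrize("pos,region,arm", [
    (30_001, "subtelomeric", "left"),      # distance 30000: inclusive
    (30_002, "mid-chromosomal", "left"),   # distance 30001
    (10, "subtelomeric", "left"),
    (499_995, "subtelomeric", "right"),
    (250_000, "mid-chromosomal", "left"),  # tie at midpoint goes left
    (250_001, "mid-chromosomal", "right"),
])
def test_classify_location(pos, region, arm):
    g = _genome()
    ref = g["chrI"][pos - 1]
    alt = "A" if ref != "A" else "C"
    assert classify_location(MutationRecord("s", "chrI", pos, ref, alt), g) \
        == (region, arm)


# ------------------------------------------------------- normalization

@pytest.mark.parametrize("ref,alt,ctx,out_cls,out_ctx", [
    ("G", "C", "CGG", "C>G", "CCG"),   # purine call flips to pyrimidine
    ("C", "G", "CCG", "C>G", "CCG"),   # identity
    ("A", "T", "TAT", "T>A", "ATA"),
])
def test_normalize_substitution(ref, alt, ctx, out_cls, out_ctx):
    assert normalize_substitution(ref, alt, ctx) == (out_cls, out_ctx)


def test_spectrum_reverse_complement_invariance(small_bundle):
    g = small_bundle.genome
    sbs = small_bundle.mutations.of_class("SBS")
    flipped_genome = g.reverse_complemented()
    flipped = MutationSet([
        MutationRecord(r.sample_id, r.chrom,
                       g.lengths[r.chrom] - r.pos + 1,
                       revcomp(r.ref), revcomp(r.alt), r.vaf)
        for r in sbs
    ])
    t1 = spectrum_table(sbs, g)
    t2 = spectrum_table(flipped, flipped_genome)
    assert t1.classes == t2.classes
    assert t1.channels == t2.channels


# ------------------------------------------------------- grouping

def test_group_adjacent_merges_runs():
    recs = [_rec(10, "A", "G"), _rec(11, "C", "T"),          # DBS
            _rec(20, "A", "G"), _rec(22, "A", "G"),          # stay SBS
            _rec(30, "A", "G"), _rec(31, "C", "T"), _rec(32, "G", "A")]  # MBS
    out = group_adjacent(MutationSet(recs))
    classes = sorted(r.mclass for r in out)
    assert classes == ["DBS", "MBS", "SBS", "SBS"]
    dbs = next(r for r in out if r.mclass == "DBS")
    assert (dbs.pos, dbs.ref, dbs.alt) == (10, "AC", "GT")


def test_group_adjacent_respects_samples():
    recs = [_rec(10, "A", "G", sample="s1"), _rec(11, "C", "T", sample="s2")]
    out = group_adjacent(MutationSet(recs))
    assert all(r.mclass == "SBS" for r in out)


# ------------------------------------------------------- strand-aware

def test_strand_resolved_spectrum_counts_sides():
    g = _genome(200_000)
    recs = [
        _rec(100, "C", "G"), _rec(204, "C", "G"), _rec(308, "C", "G"),
        _rec(199_898, "G", "C"), _rec(199_998, "G", "C"),
        _rec(100_000, "C", "A"),  # mid-chromosomal: excluded
    ]
    # fix refs to actual genome bases
    recs = [MutationRecord("s", "chrI", r.pos, g["chrI"][r.pos - 1],
                           r.alt if g["chrI"][r.pos - 1] != r.alt else "T")
            for r in recs]
    sp = strand_resolved_spectrum(MutationSet(recs), g)
    left_total = sum(sp.left_arm.values())
    right_total = sum(sp.right_arm.values())
    assert left_total == 3 and right_total == 2
    assert sp.total == 5


def test_arm_counts_conserve_total(small_bundle):
    g = small_bundle.genome
    sbs = small_bundle.mutations.of_class("SBS")
    sp = strand_resolved_spectrum(sbs, g)
    n_mid = sum(1 for r in sbs
                if classify_location(r, g)[0] == "mid-chromosomal")
    assert sp.total + n_mid == len(sbs)


def test_planted_subtelomeric_fraction_recovered(small_bundle, small_config):
    g = small_bundle.genome
    sbs = small_bundle.mutations.of_class("SBS")
    n_sub = sum(1 for r in sbs if classify_location(r, g)[0] == "subtelomeric")
    f = n_sub / len(sbs)
    # binomial 4-sigma band around the planted fraction
    p = small_config.subtelomeric_fraction
    tol = 4 * (p * (1 - p) / len(sbs)) ** 0.5
    assert abs(f - p) <= tol


def test_resection_asymmetry_visible(small_bundle):
    sp = strand_resolved_spectrum(small_bundle.mutations.of_class("SBS"),
                                  small_bundle.genome)
    left_c = sum(v for k, v in sp.left_arm.items() if k.startswith("C"))
    left_g = sum(v for k, v in sp.left_arm.items() if k.startswith("G"))
    right_c = sum(v for k, v in sp.right_arm.items() if k.startswith("C"))
    right_g = sum(v for k, v in sp.right_arm.items() if k.startswith("G"))
    assert left_c > 3 * left_g
    assert right_g > 3 * right_c


# ------------------------------------------------------- density / medians

def test_mutation_density_arithmetic():
    g = _genome(750_000)
    recs = []
    for i in range(15):
        pos = 101 + 4 * i  # lands on 'C' in the ACGT repeat? ensure below
        ref = g["chrI"][pos - 1]
        recs.append(MutationRecord("s", "chrI", pos, ref,
                                   "G" if ref != "G" else "C"))
    dens = mutation_density(MutationSet(recs), g, region_bp=750_000,
                            n_isolates=2)
    assert sum(dens.values()) == pytest.approx(15 / (2 * 750_000))
    half = mutation_density(MutationSet(recs), g, region_bp=750_000,
                            n_isolates=4)
    assert sum(half.values()) == pytest.approx(sum(dens.values()) / 2)


def test_mutation_density_zero_territory_errors(tiny_genome):
    with pytest.raises(ValueError):
        mutation_density(MutationSet([]), tiny_genome, 0, 1)


def test_subtelomeric_territory_caps_short_chromosomes():
    g = GenomeSequence({"short": "ACGT" * 1000, "long": "ACGT" * 20_000})
    cfg = SubtelomereConfig(threshold_bp=30_000)
    assert subtelomeric_territory(g, cfg) == 4_000 + 60_000


@pytest.mark.parametrize("counts,expected", [
    ({"a": 2, "b": 4, "c": 9}, 4), ({"a": 7}, 7),
    ({"a": 1, "b": 2, "c": 3, "d": 4}, 2.5),
])
def test_mutations_per_isolate_median(counts, expected):
    recs = []
    for s, n in counts.items():
        recs += [_rec(10 + i, "A", "G", sample=s) for i in range(n)]
    got, median = mutations_per_isolate(MutationSet(recs))
    assert got == counts and median == expected


def test_mutations_per_isolate_zero_count_samples():
    ms = MutationSet([_rec(10, "A", "G", sample="a")])
    counts, median = mutations_per_isolate(ms, samples=["a", "b", "c"])
    assert counts == {"a": 1, "b": 0, "c": 0} and median == 0
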