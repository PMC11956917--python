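"""Transcriptional strand bias of motif mutations.

The non-transcribed (coding) strand of an expressed gene is transiently
single-stranded inside transcription bubbles and less protected by
transcription-coupled repair, so an ssDNA-directed mutagen leaves more
motif mutations with the damaged purine on the transcribed strand —
equivalently, the pyrimidine-reported mutation on the non-transcribed
strand.  A mutation whose pyrimidine lies on strand *s* inside a gene on
strand *g* is counted as non-transcribed when ``s == g`` and transcribed
when ``s != g``; positions covered by genes on both strands, or by none,
are excluded as ambiguous/intergenic.

Counts are tested with a chi-square goodness-of-fit (1 df) against either
a 50:50 expectation (default) or an "opportunity" expectation proportional
to motif occurrences on each strand within unambiguous gene territory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats

from ._seq import Motif, PYRIMIDINES, _pattern_match, pyrimidine_class
from .io import GeneIntervals, GenomeSequence, MutationSet


@dataclass
class StrandBiasResult:
    n_transcribed: int
    n_nontranscribed: int
    n_excluded: int
    expected_model: str
    expected_nontranscribed: float
    chi2: float
    p_value: float
    corrected_p: float = 1.0
    cohort: str = "pooled"

    @property
    def nontranscribed_fraction(self) -> float:
        n = self.n_transcribed + self.n_nontranscribed
        return self.n_nontranscribed / n if n else float("nan")


def assign_transcription_strand(
    mutations: MutationSet, genes: GeneIntervals
) -> list[tuple]:
    """Label each SBS with 'transcribed', 'nontranscribed' or 'excluded'.

    Gene territory is the union of intervals per strand; a position covered
    on both strands is ambiguous, an uncovered one intergenic — both
    excluded.
    """
    trees = genes.by_strand_trees()
    labels = []
    for r in mutations.of_class("SBS"):
        i = r.pos - 1  # 0-based
        pyr_strand = "+" if r.ref in PYRIMIDINES else "-"
        on_plus = bool(trees.get((r.chrom, "+")) and trees[(r.chrom, "+")][i])
        on_minus = bool(trees.get((r.chrom, "-")) and trees[(r.chrom, "-")][i])
        if on_plus == on_minus:  # both strands or intergenic
            labels.append((r, "excluded"))
        else:
            gene_strand = "+" if on_plus else "-"
            labels.append(
                (r, "nontranscribed" if pyr_strand == gene_strand
                 else "transcribed")
            )
    return labels


def _single_strand_territory(genes: GeneIntervals, genome: GenomeSequence):
    """Per chromosome, merged intervals covered by exactly one strand,
    keyed by that strand."""
    from intervaltree import IntervalTree

    trees = genes.by_strand_trees()
    out = []  # (chrom, start, end, strand)
    for chrom in genome.names():
        plus = trees.get((chrom, "+"), IntervalTree())
        minus = trees.get((chrom, "-"), IntervalTree())
        for strand, own, other in (("+", plus, minus), ("-", minus, plus)):
            merged = IntervalTree(own)
            merged.merge_overlaps()
            for iv in sorted(merged):
                # subtract any overlap with the other strand
                cut = IntervalTree([iv])
                for ov in other.overlap(iv.begin, iv.end):
                    cut.chop(ov.begin, ov.end)
                for piece in sorted(cut):
                    out.append((chrom, piece.begin, piece.end, strand))
    return out


def motif_strand_opportunity(
    genes: GeneIntervals, genome: GenomeSequence, motif: Motif
) -> tuple[int, int]:
    """Motif occurrence counts by transcriptional strand inside unambiguous
    gene territory: (transcribed, nontranscribed).

    A forward-pattern occurrence has its pyrimidine on '+', a reverse-
    complement occurrence on '-'; within a '+'-strand gene the former is a
    non-transcribed-strand opportunity.
    """
    n_trans = 0
    n_nontrans = 0
    for chrom, start, end, strand in _single_strand_territory(genes, genome):
        seq = genome[chrom][start:end]
        fwd = _count_overlapping(seq, motif.pattern)
        rev = _count_overlapping(seq, motif.rc_pattern)
        if strand == "+":
            n_nontrans += fwd
            n_trans += rev
        else:
            n_nontrans += rev
            n_trans += fwd
    return n_trans, n_nontrans


def _count_overlapping(seq: str, pattern: str) -> int:
    m = len(pattern)
    return sum(
        _pattern_match(seq[i : i + m], pattern) for i in range(len(seq) - m + 1)
    )


def strand_bias_test(
    n_transcribed: int,
    n_nontranscribed: int,
    expected_nontranscribed: float = 0.5,
    model: str = "fifty_fifty",
) -> tuple[float, float]:
    """Chi-square goodness of fit (1 df) of the strand counts against the
    expected non-transcribed proportion.  Returns (chi2, p)."""
    n = n_transcribed + n_nontranscribed
    if n < 1:
        raise ValueError("need at least one strand-assigned mutation")
    if not 0.0 < expected_nontranscribed < 1.0:
        raise ValueError("expected proportion must be inside (0, 1)")
    exp = [n * (1 - expected_nontranscribed), n * expected_nontranscribed]
    chi2, p = stats.chisquare([n_transcribed, n_nontranscribed], f_exp=exp)
    return float(chi2), float(p)


class TranscriptionStrandBias:
    """Strand-bias model for motif mutations of one catalog.

    ``expected`` is ``fifty_fifty`` (a plain ratio test) or
    ``opportunity`` (expected proportions from motif occurrence counts per
    strand in unambiguous gene territory).
    """

    def __init__(self, mutations: MutationSet, genes: GeneIntervals,
                 genome: GenomeSequence, motif: str = "cCg",
                 substitution: str = "C>G", expected: str = "fifty_fifty",
                 cohort: str = "pooled"):
        if expected not in ("fifty_fifty", "opportunity"):
            raise ValueError("expected must be 'fifty_fifty' or 'opportunity'")
        self.mutations = mutations
        self.genes = genes
        self.genome = genome
        self.motif = Motif(motif)
        self.substitution = substitution
        self.expected = expected
        self.cohort = cohort

    def _motif_mutations(self) -> MutationSet:
        from ._seq import normalize_substitution

        keep = []
        for r in self.mutations.of_class("SBS"):
            tri = self.genome.trinucleotide(r.chrom, r.pos)
            if tri is None or "N" in tri or r.ref == "N":
                continue
            cls, ctx = normalize_substitution(r.ref, r.alt, tri)
            if cls == self.substitution and self.motif.matches_context(ctx):
                keep.append(r)
        return MutationSet(keep)

    def fit(self) -> "StrandBiasResults":
        motif_set = self._motif_mutations()
        labels = assign_transcription_strand(motif_set, self.genes)
        n_t = sum(1 for _, lab in labels if lab == "transcribed")
        n_nt = sum(1 for _, lab in labels if lab == "nontranscribed")
        n_ex = sum(1 for _, lab in labels if lab == "excluded")
        if self.expected == "fifty_fifty":
            exp_nt = 0.5
        else:
            opp_t, opp_nt = motif_strand_opportunity(
                self.genes, self.genome, self.motif)
            if opp_t == 0 or opp_nt == 0:
                raise ValueError(
                    "opportunity model: zero motif opportunity on one strand")
            exp_nt = opp_nt / (opp_t + opp_nt)
        chi2, p = strand_bias_test(n_t, n_nt, exp_nt, self.expected)
        res = StrandBiasResult(
            n_transcribed=n_t, n_nontranscribed=n_nt, n_excluded=n_ex,
            expected_model=self.expected, expected_nontranscribed=exp_nt,
            chi2=chi2, p_value=p, corrected_p=p, cohort=self.cohort,
        )
        return StrandBiasResults(self, [res])


@dataclass
class StrandBiasResults:
    model: TranscriptionStrandBias | None
    results: list[StrandBiasResult] = field(default_factory=list)

    def __iter__(self):
        return iter(self.results)

    @property
    def single(self) -> StrandBiasResult:
        if len(self.results) != 1:
            raise ValueError("more than one cohort; index .results")
        return self.results[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                dict(cohort=r.cohort, n_transcribed=r.n_transcribed,
                     n_nontranscribed=r.n_nontranscribed,
                     n_excluded=r.n_excluded, expected_model=r.expected_model,
                     expected_nontranscribed=r.expected_nontranscribed,
                     chi2=r.chi2, p_value=r.p_value, corrected_p=r.corrected_p)
                for r in self.results
            ]
        )

    def summary(self) -> str:
        lines = ["Transcriptional strand bias", "=" * 72]
        for r in self.results:
            lines.append(
                f"{r.cohort}: transcribed={r.n_transcribed} "
                f"non-transcribed={r.n_nontranscribed} "
                f"excluded={r.n_excluded} (expected NT "
                f"{r.expected_nontranscribed:.3f}, {r.expected_model})"
            )
            lines.append(
                f"  chi2(1)={r.chi2:.3f}  p={r.p_value:.3g}  "
                f"corrected p={r.corrected_p:.3g}"
            )
        lines.append("=" * 72)
        return "\n".join(lines)


def correct_across_cohorts(
    results: list[StrandBiasResult], method: str = "bh"
) -> list[StrandBiasResult]:
    """BH (default) correction across several cohorts' strand-bias tests."""
    if not results:
        return results
    from statsmodels.stats.multitest import multipletests

    ps = [r.p_value for r in results]
    if method == "bh":
        corrected = multipletests(ps, method="fdr_bh")[1]
    elif method == "bonferroni":
        corrected = [min(1.0, p * len(ps)) for p in ps]
    else:
        raise ValueError(f"unknown correction {method!r}")
    for r, cp in zip(results, corrected):
        r.corrected_p = float(cp)
    return results
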