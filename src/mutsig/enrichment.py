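"""Trinucleotide mutation-signature (TriMS) enrichment analysis.

The statistic asks whether a substitution class (say C→G, counted in
pyrimidine space so G→C on the top strand is included) occurs at a mutable
motif (say cCg, lowercase flanks fixed, uppercase mutated base) more often
than the motif's local availability predicts.  For each qualifying mutation
the ±``window_radius`` nt of top-strand sequence around it contributes to
two context tallies — occurrences of the mutated base in pyrimidine space
(``context_ref``) and occurrences of the motif or its reverse complement
(``context_motif``); windows are summed per mutation, so overlapping windows
count repeatedly.  The enrichment is the odds-style ratio

    enrichment = (mutations_motif × context_ref)
               / (mutations_total × context_motif)

tested with a one-sided Fisher's exact test on
[[mutations_motif, mutations_total − mutations_motif],
 [context_motif,  context_ref − context_motif]]
and corrected for multiple testing (Bonferroni by default).  For a
significant enrichment E > 1 the minimum mutation load

    min_load = mutations_motif × (E − 1) / E

estimates how many of the motif mutations the signature itself contributed.

The model-object interface follows the statsmodels idiom:

>>> model = TrinucleotideEnrichment(mutations, genome, motifs=["cCg"],
...                                 substitution="C>G")
>>> results = model.fit()
>>> print(results.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._seq import Motif, count_motif_occurrences, count_pattern
from .io import GenomeSequence, MutationSet


@dataclass
class EnrichmentConfig:
    """Knobs of the context-enrichment statistic.

    window_radius
        nt of top-strand context scanned on each side of every mutation
        (default 20, i.e. a 41-nt window truncated at chromosome ends).
    motif / substitution
        pattern with one uppercase mutated pyrimidine (``n`` matches any
        base) and the pyrimidine substitution class it is tested against.
    """

    motif: str = "cCg"
    substitution: str = "C>G"
    window_radius: int = 20
    alpha: float = 0.05
    correction: str = "bonferroni"

    def __post_init__(self):
        m = Motif(self.motif)
        base = self.substitution.split(">")[0]
        if m.base != base:
            raise ValueError(
                f"motif {self.motif!r} centre {m.base!r} does not match "
                f"substitution {self.substitution!r}"
            )
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")
        if self.correction not in ("bonferroni", "bh"):
            raise ValueError("correction must be 'bonferroni' or 'bh'")


@dataclass
class EnrichmentResult:
    """One motif × cohort (or motif × sample) enrichment row."""

    motif: str
    substitution: str
    sample_id: str  # "pooled" for the whole-cohort row
    mutations_motif: int
    mutations_total: int
    context_ref: int
    context_motif: int
    enrichment: float | None  # None when undefined (context_motif == 0)
    p_value: float = 1.0
    corrected_p: float = 1.0
    min_load: float = 0.0

    @property
    def undefined(self) -> bool:
        return self.enrichment is None


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _qualifying_records(mutations, genome, cfg: EnrichmentConfig):
    """SBS records of the configured pyrimidine class with N-free context.

    Records whose trinucleotide context contains N (or sits at a chromosome
    end) are excluded from all context-dependent tallies rather than
    silently shrinking only some denominators.
    """
    from ._seq import normalize_substitution

    base, alt = cfg.substitution.split(">")
    out = []
    for r in mutations.of_class("SBS"):
        if r.ref == "N" or r.alt == "N":
            continue
        tri = genome.trinucleotide(r.chrom, r.pos)
        if tri is None or "N" in tri:
            continue
        cls, ctx = normalize_substitution(r.ref, r.alt, tri)
        if cls == cfg.substitution:
            out.append((r, ctx))
    return out


def count_window_contexts(
    mutations: MutationSet, genome: GenomeSequence, cfg: EnrichmentConfig
) -> tuple[int, int]:
    """Summed ±window counts over all qualifying mutations.

    Returns ``(context_ref, context_motif)``: per mutation, the top-strand
    window contributes its count of the mutated base in pyrimidine space
    (top-strand C or G for a C-centred motif) and its count of motif
    occurrences (pattern plus reverse complement).  N bases never match.
    """
    motif = Motif(cfg.motif)
    ref_fwd = motif.base
    ref_rev = {"C": "G", "T": "A"}[motif.base]
    ctx_ref = 0
    ctx_motif = 0
    for r, _ in _qualifying_records(mutations, genome, cfg):
        window = genome.context(r.chrom, r.pos, cfg.window_radius)
        ctx_ref += window.count(ref_fwd) + window.count(ref_rev)
        ctx_motif += count_motif_occurrences(window, motif)
    return ctx_ref, ctx_motif


def compute_enrichment(
    mutations: MutationSet,
    genome: GenomeSequence,
    cfg: EnrichmentConfig,
    sample_id: str = "pooled",
) -> EnrichmentResult:
    """Assemble the four counts and the enrichment ratio for one cohort."""
    motif = Motif(cfg.motif)
    qualifying = _qualifying_records(mutations, genome, cfg)
    mutations_total = len(qualifying)
    mutations_motif = sum(
        1 for _, ctx in qualifying if motif.matches_context(ctx)
    )
    ctx_ref, ctx_motif = count_window_contexts(mutations, genome, cfg)
    if ctx_motif == 0 or mutations_total == 0:
        enrichment = None if ctx_motif == 0 else 0.0
    else:
        enrichment = (mutations_motif * ctx_ref) / (mutations_total * ctx_motif)
    return EnrichmentResult(
        motif=cfg.motif,
        substitution=cfg.substitution,
        sample_id=sample_id,
        mutations_motif=mutations_motif,
        mutations_total=mutations_total,
        context_ref=ctx_ref,
        context_motif=ctx_motif,
        enrichment=enrichment,
    )


def fisher_greater(a, b, c, d):
    """Vectorised one-sided (greater) Fisher's exact p for tables
    [[a, b], [c, d]], computed as the hypergeometric upper tail
    P(X >= a | N, a+b, a+c).  Degenerate margins give p = 1."""
    a = np.asarray(a)
    n1 = a + np.asarray(b)
    k = a + np.asarray(c)
    N = n1 + np.asarray(c) + np.asarray(d)
    p = stats.hypergeom.sf(a - 1, N, n1, k)
    # fully degenerate tables (empty support) are defined as p = 1
    p = np.where(np.isnan(p), 1.0, p)
    return np.clip(p, 0.0, 1.0)


def fisher_enrichment_test(result: EnrichmentResult) -> float:
    """One-sided Fisher's exact test of motif over-representation among
    mutations relative to the summed window contexts."""
    a = result.mutations_motif
    b = result.mutations_total - result.mutations_motif
    c = result.context_motif
    d = result.context_ref - result.context_motif
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in enrichment table")
    return float(fisher_greater(a, b, c, d))


def correct_pvalues(
    results: list[EnrichmentResult], method: str = "bonferroni",
    m: int | None = None,
) -> list[EnrichmentResult]:
    """Attach corrected p-values in place (and return the list).

    Bonferroni uses family size ``m`` (default: number of results; must be
    at least that).  BH is the standard step-up over the supplied family.
    """
    if not results:
        return results
    ps = [r.p_value for r in results]
    if method == "bonferroni":
        m = len(results) if m is None else m
        if m < len(results):
            raise ValueError("Bonferroni family smaller than number of tests")
        corrected = [min(1.0, p * m) for p in ps]
    elif method == "bh":
        from statsmodels.stats.multitest import multipletests

        corrected = list(multipletests(ps, method="fdr_bh")[1])
    else:
        raise ValueError(f"unknown correction {method!r}")
    for r, cp in zip(results, corrected):
        r.corrected_p = float(max(cp, r.p_value))
    return results


def min_mutation_load(result: EnrichmentResult, alpha: float = 0.05) -> float:
    """Minimum mutations attributable to the signature:
    mutations_motif × (E − 1)/E when E > 1 and corrected p <= alpha, else 0.
    """
    E = result.enrichment
    if E is None or E <= 1.0 or result.corrected_p > alpha:
        return 0.0
    return result.mutations_motif * (E - 1.0) / E


def trims_scan(
    mutations: MutationSet,
    genome: GenomeSequence,
    motifs: list[tuple[str, str]],
    window_radius: int = 20,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    per_sample: bool = False,
) -> list[EnrichmentResult]:
    """Run the full statistic for several (motif, substitution) pairs.

    Emits one pooled result per motif (corrected across the pooled family)
    and, with ``per_sample``, one result per sample per motif (corrected
    within that motif across samples).
    """
    pooled: list[EnrichmentResult] = []
    per_sample_rows: list[EnrichmentResult] = []
    for motif, substitution in motifs:
        cfg = EnrichmentConfig(motif=motif, substitution=substitution,
                               window_radius=window_radius, alpha=alpha,
                               correction=correction)
        res = compute_enrichment(mutations, genome, cfg)
        res.p_value = fisher_enrichment_test(res)
        pooled.append(res)
        if per_sample:
            rows = []
            for sample, recs in mutations.by_sample().items():
                sub = MutationSet(list(recs))
                r = compute_enrichment(sub, genome, cfg, sample_id=sample)
                r.p_value = fisher_enrichment_test(r)
                rows.append(r)
            correct_pvalues(rows, correction)
            for r in rows:
                r.min_load = min_mutation_load(r, alpha)
            per_sample_rows.extend(rows)
    correct_pvalues(pooled, correction)
    for r in pooled:
        r.min_load = min_mutation_load(r, alpha)
    return pooled + per_sample_rows


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class TrinucleotideEnrichment:
    """Context-corrected motif enrichment model for a mutation catalog.

    Parameters
    ----------
    mutations, genome
        the catalog and the reference it was called against.
    motifs
        motif patterns (e.g. ``["cCg", "nCg"]``); each is tested against
        ``substitution``, or supply ``(motif, substitution)`` pairs.
    """

    def __init__(self, mutations: MutationSet, genome: GenomeSequence,
                 motifs=("cCg",), substitution: str = "C>G",
                 window_radius: int = 20, alpha: float = 0.05,
                 correction: str = "bonferroni"):
        self.mutations = mutations
        self.genome = genome
        self.motifs = [
            m if isinstance(m, tuple) else (m, substitution) for m in motifs
        ]
        self.window_radius = window_radius
        self.alpha = alpha
        self.correction = correction

    def fit(self, per_sample: bool = False) -> "EnrichmentResults":
        rows = trims_scan(self.mutations, self.genome, self.motifs,
                          window_radius=self.window_radius, alpha=self.alpha,
                          correction=self.correction, per_sample=per_sample)
        return EnrichmentResults(self, rows)


@dataclass
class EnrichmentResults:
    """Fitted enrichment table with statsmodels-style accessors."""

    model: TrinucleotideEnrichment
    results: list[EnrichmentResult] = field(default_factory=list)

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    @property
    def pooled(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.sample_id == "pooled"]

    def get(self, motif: str, sample_id: str = "pooled") -> EnrichmentResult:
        for r in self.results:
            if r.motif == motif and r.sample_id == sample_id:
                return r
        raise KeyError((motif, sample_id))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                dict(motif=r.motif, substitution=r.substitution,
                     sample=r.sample_id, mutations_motif=r.mutations_motif,
                     mutations_total=r.mutations_total,
                     context_ref=r.context_ref, context_motif=r.context_motif,
                     enrichment=r.enrichment, p_value=r.p_value,
                     corrected_p=r.corrected_p, min_load=r.min_load)
                for r in self.results
            ]
        )

    def summary(self) -> str:
        lines = [
            "Trinucleotide motif enrichment",
            "=" * 78,
            f"{'motif':<8}{'subst':<7}{'sample':<10}{'n_motif':>8}"
            f"{'n_total':>8}{'enrich':>9}{'p':>11}{'p_corr':>11}{'load':>9}",
            "-" * 78,
        ]
        for r in self.results:
            enr = "undef" if r.enrichment is None else f"{r.enrichment:.3f}"
            lines.append(
                f"{r.motif:<8}{r.substitution:<7}{r.sample_id:<10}"
                f"{r.mutations_motif:>8}{r.mutations_total:>8}{enr:>9}"
                f"{r.p_value:>11.3g}{r.corrected_p:>11.3g}{r.min_load:>9.2f}"
            )
        lines.append("=" * 78)
        return "\n".join(lines)

    def plot(self, ax=None):  # pragma: no cover - convenience only
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pooled = self.pooled
        xs = [r.motif for r in pooled]
        ys = [r.enrichment if r.enrichment is not None else 0 for r in pooled]
        ax.bar(xs, ys)
        ax.axhline(1.0, ls="--", color="k", lw=0.8)
        ax.set_ylabel("enrichment")
        return ax
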