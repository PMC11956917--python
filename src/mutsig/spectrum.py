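"""Mutation spectra for resected-telomere ssDNA hypermutation experiments.

In the telomere-uncapping (cdc13-1) system, 5'→3' resection from both
chromosome ends exposes long single-stranded tails; mutations therefore
concentrate within ~30 kb of telomeres ("sub-telomeric") and show reciprocal
top-strand asymmetry between left and right arms, because the exposed
(bottom) strand differs between arms.  This module classifies calls by
telomere distance and arm, produces pyrimidine-normalized 6-class and
96-channel spectra, strand-aware (uncollapsed, 12-class) left/right spectra,
per-isolate mutation loads and per-bp densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import (PYR_CLASSES, TOP_STRAND_CLASSES, normalize_substitution,
                   pyrimidine_class)
from .io import GenomeSequence, MutationRecord, MutationSet

# re-exported: the spec-level operation lives here conceptually
normalize_substitution = normalize_substitution


@dataclass
class SubtelomereConfig:
    """Distance threshold separating sub-telomeric from mid-chromosomal
    territory.  30 kb is how far resection-derived ssDNA extends from yeast
    telomere ends; the boundary is inclusive (distance <= threshold)."""

    threshold_bp: int = 30_000

    def __post_init__(self):
        if self.threshold_bp <= 0:
            raise ValueError("threshold_bp must be positive")


def telomere_distance(record: MutationRecord, genome: GenomeSequence) -> int:
    """Distance (bp) from the nearest telomere end: min(pos-1, L-pos).

    For multi-base records the first reference base is used.
    """
    if record.chrom not in genome:
        raise KeyError(f"unknown chromosome {record.chrom!r}")
    L = genome.lengths[record.chrom]
    return min(record.pos - 1, L - record.pos)


def classify_location(
    record: MutationRecord,
    genome: GenomeSequence,
    cfg: SubtelomereConfig | None = None,
) -> tuple[str, str]:
    """Return (region, arm): region is 'subtelomeric' iff the telomere
    distance is <= the threshold; arm is 'left' iff pos-1 <= L-pos (a tie at
    the exact midpoint goes left)."""
    cfg = cfg or SubtelomereConfig()
    L = genome.lengths[record.chrom]
    d = telomere_distance(record, genome)
    region = "subtelomeric" if d <= cfg.threshold_bp else "mid-chromosomal"
    arm = "left" if record.pos - 1 <= L - record.pos else "right"
    return region, arm


@dataclass
class SpectrumTable:
    """Pyrimidine-normalized substitution counts: the six classes plus,
    optionally, the 96 trinucleotide channels (e.g. ``A[C>G]T``)."""

    classes: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in PYR_CLASSES})
    channels: dict[str, int] = field(default_factory=dict)
    n_flagged: int = 0  # N in base or context: kept out of channel counts

    @property
    def total(self) -> int:
        return sum(self.classes.values())

    def to_frame(self):
        import pandas as pd

        rows = [{"class": c, "count": n} for c, n in self.classes.items()]
        return pd.DataFrame(rows)

    def channels_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"channel": ch, "count": n} for ch, n in sorted(self.channels.items())]
        )

    def plot(self, ax=None):  # pragma: no cover - convenience only
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(list(self.classes), list(self.classes.values()))
        ax.set_ylabel("mutations")
        return ax


def spectrum_table(mutations: MutationSet, genome: GenomeSequence) -> SpectrumTable:
    """Build the pyrimidine-normalized spectrum of all SBS records."""
    table = SpectrumTable()
    for r in mutations.of_class("SBS"):
        if r.ref == "N" or r.alt == "N":
            table.n_flagged += 1
            continue
        table.classes[pyrimidine_class(r.ref, r.alt)] += 1
        tri = genome.trinucleotide(r.chrom, r.pos)
        if tri is None or "N" in tri:
            table.n_flagged += 1
            continue
        cls, ctx = normalize_substitution(r.ref, r.alt, tri)
        table.channels[f"{ctx[0]}[{cls}]{ctx[2]}"] = (
            table.channels.get(f"{ctx[0]}[{cls}]{ctx[2]}", 0) + 1
        )
    return table


@dataclass
class StrandAwareSpectrum:
    """Top-strand (uncollapsed) substitution counts for sub-telomeric SBS,
    split by chromosome arm.  Reciprocal resection predicts e.g. C→G excess
    on left arms mirrored by G→C excess on right arms."""

    left_arm: dict[str, int]
    right_arm: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.left_arm.values()) + sum(self.right_arm.values())

    def to_frame(self):
        import pandas as pd

        rows = []
        for arm, counts in (("left", self.left_arm), ("right", self.right_arm)):
            for cls, n in counts.items():
                rows.append({"arm": arm, "class": cls, "count": n})
        return pd.DataFrame(rows)


def strand_resolved_spectrum(
    mutations: MutationSet,
    genome: GenomeSequence,
    cfg: SubtelomereConfig | None = None,
) -> StrandAwareSpectrum:
    """Tabulate top-strand substitutions of sub-telomeric SBS separately for
    left and right arms, without pyrimidine collapsing."""
    cfg = cfg or SubtelomereConfig()
    left = {c: 0 for c in TOP_STRAND_CLASSES}
    right = {c: 0 for c in TOP_STRAND_CLASSES}
    for r in mutations.of_class("SBS"):
        if r.ref == "N" or r.alt == "N":
            continue
        region, arm = classify_location(r, genome, cfg)
        if region != "subtelomeric":
            continue
        (left if arm == "left" else right)[f"{r.ref}>{r.alt}"] += 1
    return StrandAwareSpectrum(left, right)


def group_adjacent(mutations: MutationSet) -> MutationSet:
    """Merge runs of adjacent same-sample SBS into DBS/MBS records.

    Upstream callers may report tandem substitutions as separate SNV rows;
    runs of k consecutive positions collapse into one record of length k.
    Non-adjacent records pass through untouched.
    """
    merged: list[MutationRecord] = []
    passthrough = [r for r in mutations if r.mclass != "SBS"]
    for sample, recs in mutations.of_class("SBS").by_sample().items():
        recs = sorted(recs, key=lambda r: (r.chrom, r.pos))
        run: list[MutationRecord] = []

        def flush():
            if not run:
                return
            if len(run) == 1:
                merged.append(run[0])
            else:
                merged.append(
                    MutationRecord(
                        sample_id=sample,
                        chrom=run[0].chrom,
                        pos=run[0].pos,
                        ref="".join(r.ref for r in run),
                        alt="".join(r.alt for r in run),
                        vaf=run[0].vaf,
                    )
                )
            run.clear()

        for r in recs:
            if run and r.chrom == run[-1].chrom and r.pos == run[-1].pos + 1:
                run.append(r)
            else:
                flush()
                run.append(r)
        flush()
    prov = dict(mutations.provenance)
    prov.setdefault("filters", []).append("group_adjacent")
    return MutationSet(merged + passthrough, prov)


def subtelomeric_territory(
    genome: GenomeSequence, cfg: SubtelomereConfig | None = None
) -> int:
    """Default ssDNA territory: two arms × threshold per chromosome, capped
    at the chromosome length."""
    cfg = cfg or SubtelomereConfig()
    return sum(min(L, 2 * cfg.threshold_bp) for L in genome.lengths.values())


def mutation_density(
    mutations: MutationSet,
    genome: GenomeSequence,
    region_bp: int,
    n_isolates: int,
) -> dict[str, float]:
    """Mutations per isolate per bp, by cumulative pyrimidine class.

    Cumulative means pyrimidine + reverse complement (a "C>G" density counts
    both C→G and G→C calls).  The caller supplies the territory size and any
    region pre-filtering of the set.
    """
    if region_bp <= 0:
        raise ValueError("region_bp must be positive")
    if n_isolates < 1:
        raise ValueError("n_isolates must be >= 1")
    table = spectrum_table(mutations, genome)
    denom = n_isolates * region_bp
    return {cls: count / denom for cls, count in table.classes.items()}


def mutations_per_isolate(
    mutations: MutationSet, samples: list[str] | None = None
) -> tuple[dict[str, int], float]:
    """Per-sample mutation counts and the median over samples.

    Samples with zero calls enter the median only when the full sample list
    is supplied.  Even-n median is the mean of the middle two.
    """
    counts = {s: len(rs) for s, rs in mutations.by_sample().items()}
    if samples is not None:
        counts = {s: counts.get(s, 0) for s in samples}
    if not counts:
        return {}, float("nan")
    return counts, float(np.median(list(counts.values())))
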