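"""Synthetic genomes, gene annotations and mutation catalogs.

The generator emulates the data-generating structure of a resected-telomere
ssDNA hypermutation experiment so that every analysis stage has
download-free, parameter-recovery tests:

* i.i.d. genomes at a configurable GC content (default 0.38, budding-yeast
  like), 16 chromosomes;
* per-isolate SBS catalogs with a planted sub-telomeric concentration,
  reciprocal left/right-arm strand asymmetry (5'→3' resection exposes the
  bottom strand, so left arms accumulate top-strand C-reference events and
  right arms the mirror image), and a planted motif enrichment;
* templated insertions (Rm→RMm), deletions in C/G runs, donor-templated
  DBS/MBS events with exact planted counts and fractions;
* non-overlapping stranded gene annotations and motif catalogs with a
  planted transcriptional strand bias.

Motif enrichment is planted by exact site enumeration: every genome
position of the reference base is classified (motif/non-motif, region, arm,
top-strand base) and its ±window context statistics are precomputed, then
the per-event probability q of drawing a motif site is solved from the
requirement that the expectation of the context-corrected enrichment
estimator equals the target E*.  Because each mutation's own window always
contains its central motif occurrence, q differs from the naive E*×(motif
fraction); the quadratic solved here accounts for that.  Sites are sampled
without replacement, so requesting more events than available sites is an
error, and no two events ever collide.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from ._seq import Motif, complement
from .io import (GeneInterval, GeneIntervals, GenomeSequence, MutationRecord,
                 MutationSet, write_fasta, write_genes_bed,
                 write_mutations_tsv, write_mutations_vcf)

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate("ACGTN")}

_STAGES = ("genome", "sbs", "indels", "genes", "strandbias")

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI",
          "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX"]


def _chrom_name(i: int) -> str:
    return f"chr{_ROMAN[i]}" if i < len(_ROMAN) else f"chr{i + 1}"


@dataclass
class SyntheticConfig:
    """All generator knobs.  Defaults encode the study conditions: a
    16-chromosome GC=0.38 genome, 114 isolates averaging 761/114 ≈ 6.7 SBS,
    91% of events within 30 kb of an end, strong reciprocal strand
    asymmetry, a cCg→G motif planted at enrichment 4, and 78 INDELs
    (45 insertions / 33 deletions), 21 DBS and 5 MBS with the observed
    templated fractions."""

    seed: int
    n_chromosomes: int = 16
    chrom_length: int = 750_000
    gc_content: float = 0.38
    n_isolates: int = 114
    sbs_per_isolate: float = 761 / 114
    motif: str = "cCg"
    substitution: str = "C>G"
    target_enrichment: float = 4.0
    subtelomeric_fraction: float = 0.91
    subtelomere_bp: int = 30_000
    strand_asymmetry: float = 0.95
    left_arm_fraction: float = 0.5
    window_radius: int = 20
    class_weights: dict = field(default_factory=lambda: {
        "C>G": 0.42, "C>A": 0.27, "C>T": 0.25,
        "T>A": 0.02, "T>C": 0.02, "T>G": 0.02,
    })
    indel_count: int = 78
    insertion_fraction: float = 45 / 78
    templated_insertion_fraction: float = 0.9
    cg_anchor_fraction: float = 33 / 45
    run_deletion_fraction: float = 0.4
    run_min_len: int = 3
    dbs_count: int = 21
    mbs_count: int = 5
    templated_dbs_fraction: float = 0.9
    templated_mbs_fraction: float = 0.8
    donor_window: int = 10
    gene_density: float = 0.7
    mean_gene_length: int = 1_500
    nontranscribed_fraction: float = 0.75

    def __post_init__(self):
        fracs = dict(
            gc_content=self.gc_content,
            subtelomeric_fraction=self.subtelomeric_fraction,
            strand_asymmetry=self.strand_asymmetry,
            left_arm_fraction=self.left_arm_fraction,
            insertion_fraction=self.insertion_fraction,
            templated_insertion_fraction=self.templated_insertion_fraction,
            cg_anchor_fraction=self.cg_anchor_fraction,
            run_deletion_fraction=self.run_deletion_fraction,
            templated_dbs_fraction=self.templated_dbs_fraction,
            templated_mbs_fraction=self.templated_mbs_fraction,
            gene_density=self.gene_density,
            nontranscribed_fraction=self.nontranscribed_fraction,
        )
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {v}")
        if self.target_enrichment < 0:
            raise ValueError("target_enrichment must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if abs(sum(self.class_weights.values()) - 1.0) > 1e-9:
            raise ValueError("class_weights must sum to 1")


def _stage_rng(cfg: SyntheticConfig, stage: str) -> np.random.Generator:
    """One independent stream per generator stage, all derived from the
    master seed, so adding stages never perturbs earlier draws."""
    idx = _STAGES.index(stage)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(idx,))
    )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(cfg: SyntheticConfig) -> GenomeSequence:
    if cfg.chrom_length < 100 or cfg.n_chromosomes < 1:
        raise ValueError("degenerate genome dimensions")
    rng = _stage_rng(cfg, "genome")
    gc = cfg.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    lut = np.frombuffer(b"ACGT", dtype="S1")
    chroms = {}
    for i in range(cfg.n_chromosomes):
        codes = rng.choice(4, size=cfg.chrom_length, p=p)
        chroms[_chrom_name(i)] = lut[codes].tobytes().decode("ascii")
    return GenomeSequence(chroms)


# ---------------------------------------------------------------------------
# SBS catalog with planted structure
# ---------------------------------------------------------------------------

def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.translate(
        str.maketrans("ACGTN", "\x00\x01\x02\x03\x04")).encode("latin1"),
        dtype=np.uint8)


def _pattern_starts(codes: np.ndarray, pattern: str) -> np.ndarray:
    """Boolean array over start positions where *pattern* matches
    (N wildcard in the pattern; N in the sequence never matches)."""
    n, m = len(codes), len(pattern)
    if n < m:
        return np.zeros(0, dtype=bool)
    ok = np.ones(n - m + 1, dtype=bool)
    for j, ch in enumerate(pattern):
        window = codes[j : n - m + 1 + j]
        if ch == "N":
            ok &= window != 4
        else:
            ok &= window == _CODE[ch]
    return ok


def _window_sum(indicator: np.ndarray, lo_off: int, hi_off: int) -> np.ndarray:
    """For every position i, sum of indicator over [i+lo_off, i+hi_off]
    intersected with the array bounds."""
    n = len(indicator)
    cs = np.concatenate([[0], np.cumsum(indicator)])
    idx = np.arange(n)
    lo = np.clip(idx + lo_off, 0, n)
    hi = np.clip(idx + hi_off + 1, 0, n)
    return cs[hi] - cs[lo]


@dataclass
class _SitePool:
    """Candidate mutation sites for one reference base in pyrimidine space."""

    chrom_idx: np.ndarray   # per-site chromosome index
    pos0: np.ndarray        # 0-based positions
    top_is_pyr: np.ndarray  # True: pyrimidine on the top strand
    is_motif: np.ndarray
    w_ref: np.ndarray       # ±R window count of the ref base (both strands)
    w_occ: np.ndarray       # ±R window count of motif occurrences
    region: np.ndarray      # 0 subtel-left, 1 subtel-right, 2 mid


def _enumerate_sites(genome: GenomeSequence, cfg: SyntheticConfig,
                     base: str) -> _SitePool:
    motif = Motif(cfg.motif) if base == Motif(cfg.motif).base else None
    comp = complement(base)
    R = cfg.window_radius
    chrom_idx, pos0, toppyr, ismot, wref, wocc, region = ([] for _ in range(7))
    for ci, name in enumerate(genome.names()):
        seq = genome[name]
        codes = _codes(seq)
        n = len(codes)
        is_fwd = codes == _CODE[base]
        is_rev = codes == _CODE[comp]
        is_ref = is_fwd | is_rev
        sites = np.flatnonzero(is_ref)
        if motif is not None:
            m = len(motif)
            s1 = _pattern_starts(codes, motif.pattern)
            s2 = (_pattern_starts(codes, motif.rc_pattern)
                  if motif.rc_pattern != motif.pattern
                  else np.zeros_like(s1))
            occ_start = np.zeros(n, dtype=np.int64)
            occ_start[: len(s1)] += s1
            occ_start[: len(s2)] += s2
            # site is a motif site iff an occurrence is centred on it
            centre1 = np.zeros(n, dtype=bool)
            centre2 = np.zeros(n, dtype=bool)
            st1 = np.flatnonzero(s1)
            centre1[st1 + motif.offset_left] = True
            st2 = np.flatnonzero(s2)
            centre2[st2 + motif.offset_right] = True
            site_motif = (centre1 | centre2)[sites]
            # occurrences fully inside the ±R window around i start at
            # t in [i-R, i+R-m+1]
            w_occ_all = _window_sum(occ_start, -R, R - m + 1)
            w_ref_all = _window_sum(is_ref.astype(np.int64), -R, R)
            site_wocc = w_occ_all[sites]
            site_wref = w_ref_all[sites]
        else:
            site_motif = np.zeros(len(sites), dtype=bool)
            site_wocc = np.zeros(len(sites), dtype=np.int64)
            site_wref = _window_sum(is_ref.astype(np.int64), -R, R)[sites]
        dist = np.minimum(sites, n - 1 - sites)
        left = sites <= (n - 1 - sites)
        reg = np.where(dist <= cfg.subtelomere_bp,
                       np.where(left, 0, 1), 2)
        chrom_idx.append(np.full(len(sites), ci))
        pos0.append(sites)
        toppyr.append(is_fwd[sites] if base in "CT" else is_rev[sites])
        ismot.append(site_motif)
        wref.append(site_wref)
        wocc.append(site_wocc)
        region.append(reg)
    return _SitePool(
        chrom_idx=np.concatenate(chrom_idx),
        pos0=np.concatenate(pos0),
        top_is_pyr=np.concatenate(toppyr),
        is_motif=np.concatenate(ismot),
        w_ref=np.concatenate(wref),
        w_occ=np.concatenate(wocc),
        region=np.concatenate(region),
    )


def _cell_probabilities(cfg: SyntheticConfig, asym: float):
    """(region, top-strand-pyrimidine) cell probabilities.

    Resection exposes the bottom strand: on left arms the damaged purine
    sits on the bottom strand with probability ``asym``, which reports as a
    top-strand pyrimidine event; right arms are reciprocal.
    """
    f = cfg.subtelomeric_fraction
    la = cfg.left_arm_fraction
    out = {}
    out[(0, True)] = f * la * asym
    out[(0, False)] = f * la * (1 - asym)
    out[(1, True)] = f * (1 - la) * (1 - asym)
    out[(1, False)] = f * (1 - la) * asym
    out[(2, True)] = (1 - f) * 0.5
    out[(2, False)] = (1 - f) * 0.5
    return out


def _solve_motif_probability(pool: _SitePool, cells: dict,
                             target: float) -> float:
    """Solve for q, the per-event probability of drawing a motif site, such
    that the expected context-corrected enrichment equals *target*."""
    if target == 0:
        return 0.0
    mbar_m = mbar_n = rbar_m = rbar_n = 0.0
    for (reg, pyr), p_cell in cells.items():
        if p_cell == 0:
            continue
        mask = (pool.region == reg) & (pool.top_is_pyr == pyr)
        mot = mask & pool.is_motif
        non = mask & ~pool.is_motif
        if mot.sum() == 0 or non.sum() == 0:
            raise ValueError(
                "genome too small: a required site bucket is empty")
        mbar_m += p_cell * pool.w_occ[mot].mean()
        mbar_n += p_cell * pool.w_occ[non].mean()
        rbar_m += p_cell * pool.w_ref[mot].mean()
        rbar_n += p_cell * pool.w_ref[non].mean()

    def g(q):
        return (q * (q * rbar_m + (1 - q) * rbar_n)
                - target * (q * mbar_m + (1 - q) * mbar_n))

    if g(1.0) < 0:
        raise ValueError(
            f"target enrichment {target} not attainable under the summed "
            f"±window convention (max ≈ {rbar_m / mbar_m:.2f})")
    if g(1.0) == 0:
        return 1.0
    return float(brentq(g, 0.0, 1.0))


def spike_sbs(genome: GenomeSequence, cfg: SyntheticConfig) -> MutationSet:
    """Draw the full SBS catalog with planted sub-telomeric fraction,
    resection strand asymmetry, and motif enrichment for the target class.

    Non-target classes share the positional structure (region and strand)
    but are drawn uniformly over reference-base sites, so only the target
    (motif, substitution) pair carries a planted enrichment.
    """
    rng = _stage_rng(cfg, "sbs")
    motif = Motif(cfg.motif)
    total = int(round(cfg.n_isolates * cfg.sbs_per_isolate))
    classes = list(cfg.class_weights)
    n_per_class = rng.multinomial(total, [cfg.class_weights[c] for c in classes])

    pools = {}
    for base in ("C", "T"):
        if any(c.startswith(base) for c in classes):
            pools[base] = _enumerate_sites(genome, cfg, base)

    names = genome.names()
    records: list[MutationRecord] = []
    # per-base bucket cursors: shuffled site indices per (region, pyr, motif)
    cursors: dict = {}
    motif_fracs: dict = {}

    def motif_fraction(base, reg, pyr):
        key = (base, reg, pyr)
        if key not in motif_fracs:
            pool = pools[base]
            mask = (pool.region == reg) & (pool.top_is_pyr == pyr)
            n = int(mask.sum())
            motif_fracs[key] = (mask & pool.is_motif).sum() / n if n else 0.0
        return motif_fracs[key]

    def draw_site(base, reg, pyr, want_motif):
        key = (base, reg, pyr, bool(want_motif))
        if key not in cursors:
            pool = pools[base]
            mask = ((pool.region == reg) & (pool.top_is_pyr == pyr)
                    & (pool.is_motif == bool(want_motif)))
            idx = np.flatnonzero(mask)
            cursors[key] = [rng.permutation(idx), 0]
        order, ptr = cursors[key]
        if ptr >= len(order):
            raise ValueError(
                f"requested events exceed available sites in bucket {key}")
        cursors[key][1] += 1
        return cursors[key][0][ptr]

    for cls, n_cls in zip(classes, n_per_class):
        if n_cls == 0:
            continue
        base, altbase = cls.split(">")
        pool = pools[base]
        is_target = (cls == cfg.substitution and base == motif.base)
        asym = cfg.strand_asymmetry if base == "C" else 0.5
        cells = _cell_probabilities(cfg, asym)
        if is_target:
            q = _solve_motif_probability(pool, cells, cfg.target_enrichment)
        else:
            q = None  # motif-unconstrained: uniform within the cell
        cell_keys = list(cells)
        cell_p = np.array([cells[k] for k in cell_keys])
        cell_draws = rng.choice(len(cell_keys), size=n_cls, p=cell_p)
        for cd in cell_draws:
            reg, pyr = cell_keys[cd]
            if q is None:
                # uniform over the cell = motif flag drawn at the cell's
                # own motif fraction
                want = rng.random() < motif_fraction(base, reg, pyr)
            else:
                want = rng.random() < q
            si = draw_site(base, reg, pyr, want)
            pos0 = int(pool.pos0[si])
            chrom = names[int(pool.chrom_idx[si])]
            ref = genome[chrom][pos0]
            alt = altbase if pool.top_is_pyr[si] else complement(altbase)
            records.append(
                MutationRecord(
                    sample_id=f"iso{rng.integers(cfg.n_isolates) + 1:03d}",
                    chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                    vaf=float(np.round(rng.uniform(0.92, 1.0), 4)),
                )
            )
    records.sort(key=lambda r: (r.chrom, r.pos, r.sample_id))
    return MutationSet(records, provenance={"source": "synthetic spike_sbs"})


# ---------------------------------------------------------------------------
# indels / DBS / MBS
# ---------------------------------------------------------------------------

def _region_ok(genome, chrom, pos0, cfg, rng_draw_subtel) -> bool:
    L = genome.lengths[chrom]
    d = min(pos0, L - 1 - pos0)
    return (d <= cfg.subtelomere_bp) == rng_draw_subtel


def _random_position(genome, cfg, rng, margin: int):
    """Uniform position honouring the sub-telomeric fraction."""
    names = genome.names()
    want_subtel = rng.random() < cfg.subtelomeric_fraction
    for _ in range(10_000):
        chrom = names[rng.integers(len(names))]
        L = genome.lengths[chrom]
        if want_subtel:
            arm_left = rng.random() < 0.5
            hi = min(cfg.subtelomere_bp, L - 1)
            off = rng.integers(margin, max(margin + 1, hi - margin))
            pos0 = off if arm_left else L - 1 - off
        else:
            pos0 = rng.integers(margin, L - margin)
            if min(pos0, L - 1 - pos0) <= cfg.subtelomere_bp:
                continue
        return chrom, int(pos0)
    raise ValueError("could not place an event honouring the region mix")


def spike_indels_dbs(genome: GenomeSequence, cfg: SyntheticConfig) -> MutationSet:
    """Plant insertions, deletions, DBS and MBS with exact counts and
    templated fractions.  Templated insertions duplicate the base(s) after
    a chosen anchor; untemplated ones insert a base differing from both
    neighbours; templated DBS/MBS copy a donor tract from within
    ±donor_window; run deletions remove one base from a C/G run."""
    from .slippage import SlippageConfig, classify_deletion, classify_record

    rng = _stage_rng(cfg, "indels")
    scfg = SlippageConfig(donor_window=cfg.donor_window,
                          run_min_len=cfg.run_min_len)
    used: set = set()
    records: list[MutationRecord] = []

    def claim(chrom, lo, hi) -> bool:
        span = {(chrom, p) for p in range(lo, hi + 1)}
        if span & used:
            return False
        used.update(span)
        return True

    def sample_id():
        return f"iso{rng.integers(cfg.n_isolates) + 1:03d}"

    n_ins = int(round(cfg.indel_count * cfg.insertion_fraction))
    n_del = cfg.indel_count - n_ins
    n_ins_t = int(round(n_ins * cfg.templated_insertion_fraction))
    n_del_run = int(round(n_del * cfg.run_deletion_fraction))
    n_dbs_t = int(round(cfg.dbs_count * cfg.templated_dbs_fraction))
    n_mbs_t = int(round(cfg.mbs_count * cfg.templated_mbs_fraction))

    ins_lengths = rng.choice([1, 2, 3], size=n_ins, p=[0.6, 0.25, 0.15])

    # templated insertions: duplicate the downstream tract after the anchor
    made = 0
    attempts = 0
    while made < n_ins_t:
        attempts += 1
        if attempts > 200_000:
            raise ValueError("insufficient eligible sites for insertions")
        chrom, i = _random_position(genome, cfg, rng, margin=10)
        seq = genome[chrom]
        want_cg = rng.random() < cfg.cg_anchor_fraction
        if (seq[i] in "CG") != want_cg:
            continue
        L = int(ins_lengths[made])
        tract = seq[i + 1 : i + 1 + L]
        if len(tract) < L or "N" in tract or "N" == seq[i]:
            continue
        if not claim(chrom, i, i + L):
            continue
        records.append(MutationRecord(sample_id(), chrom, i + 1,
                                      seq[i], seq[i] + tract, vaf=0.95))
        made += 1

    # untemplated insertions: single base differing from both neighbours
    made = 0
    while made < n_ins - n_ins_t:
        chrom, i = _random_position(genome, cfg, rng, margin=10)
        seq = genome[chrom]
        if seq[i] == "N" or seq[i + 1] == "N":
            continue
        options = [b for b in _BASES if b not in (seq[i], seq[i + 1])]
        b = options[rng.integers(len(options))]
        if not claim(chrom, i, i + 1):
            continue
        records.append(MutationRecord(sample_id(), chrom, i + 1,
                                      seq[i], seq[i] + b, vaf=0.95))
        made += 1

    # run deletions: one base out of a C/G run of >= run_min_len
    made = 0
    attempts = 0
    while made < n_del_run:
        attempts += 1
        if attempts > 200_000:
            raise ValueError("insufficient C/G runs for run deletions")
        chrom, i = _random_position(genome, cfg, rng, margin=10)
        seq = genome[chrom]
        if seq[i + 1] not in "CG":
            continue
        letter = seq[i + 1]
        j = i + 1
        run_len = 0
        while j + run_len < len(seq) and seq[j + run_len] == letter:
            run_len += 1
        k = j
        while k > 0 and seq[k - 1] == letter:
            k -= 1
            run_len += 1
        if run_len < cfg.run_min_len or seq[i] == letter:
            continue
        if not claim(chrom, i, i + 1):
            continue
        records.append(MutationRecord(sample_id(), chrom, i + 1,
                                      seq[i] + seq[i + 1], seq[i], vaf=0.95))
        made += 1

    # other deletions: 1-5 bp tracts that the run rule does not claim
    made = 0
    attempts = 0
    while made < n_del - n_del_run:
        attempts += 1
        if attempts > 200_000:
            raise ValueError("insufficient sites for non-run deletions")
        chrom, i = _random_position(genome, cfg, rng, margin=12)
        seq = genome[chrom]
        L = int(rng.integers(1, 6))
        tract = seq[i + 1 : i + 1 + L]
        if len(tract) < L or "N" in tract or seq[i] == "N":
            continue
        rec = MutationRecord(sample_id(), chrom, i + 1,
                             seq[i] + tract, seq[i], vaf=0.95)
        if classify_deletion(rec, genome, scfg).templated:
            continue
        if not claim(chrom, i, i + L):
            continue
        records.append(rec)
        made += 1

    # DBS / MBS
    for length, total_n, n_templated in (
        (2, cfg.dbs_count, n_dbs_t),
        (None, cfg.mbs_count, n_mbs_t),
    ):
        made_t = made_u = 0
        attempts = 0
        while made_t + made_u < total_n:
            attempts += 1
            if attempts > 500_000:
                raise ValueError("insufficient sites for DBS/MBS events")
            L = length or int(rng.integers(3, 6))
            chrom, i = _random_position(genome, cfg, rng,
                                        margin=cfg.donor_window + L + 2)
            seq = genome[chrom]
            ref = seq[i : i + L]
            if "N" in ref:
                continue
            if L == 2 and not any(b in "CG" for b in ref):
                continue  # doublets predominantly carry a C or G
            templated = made_t < n_templated
            if templated:
                offs = [d for s in (1, -1)
                        for d in range(s * L, s * (cfg.donor_window + 1), s)]
                rng.shuffle(offs)
                alt = None
                for d in offs:
                    donor = seq[i + d : i + d + L]
                    if len(donor) < L or "N" in donor:
                        continue
                    if donor[0] != ref[0] and donor[-1] != ref[-1]:
                        alt = donor
                        break
                if alt is None:
                    continue
            else:
                alt = "".join(
                    _BASES[rng.integers(4)] if 0 < j < L - 1
                    else [b for b in _BASES if b != ref[j]][rng.integers(3)]
                    for j in range(L)
                )
                rec = MutationRecord(sample_id(), chrom, i + 1, ref, alt,
                                     vaf=0.95)
                if classify_record(rec, genome, scfg).templated:
                    continue
            if not claim(chrom, i - 1, i + L):
                continue
            records.append(MutationRecord(sample_id(), chrom, i + 1,
                                          ref, alt, vaf=0.95))
            if templated:
                made_t += 1
            else:
                made_u += 1

    records.sort(key=lambda r: (r.chrom, r.pos, r.sample_id))
    return MutationSet(records, provenance={"source": "synthetic spike_indels_dbs"})


# ---------------------------------------------------------------------------
# genes and transcriptional strand bias
# ---------------------------------------------------------------------------

def generate_genes(genome: GenomeSequence, cfg: SyntheticConfig) -> GeneIntervals:
    """Non-overlapping stranded genes at the configured density."""
    if cfg.gene_density == 0:
        return GeneIntervals([])
    if cfg.gene_density > 0.9:
        raise ValueError("gene_density too high to place without overlap")
    rng = _stage_rng(cfg, "genes")
    mean_gap = cfg.mean_gene_length * (1 - cfg.gene_density) / cfg.gene_density
    intervals = []
    gid = 0
    for chrom in genome.names():
        L = genome.lengths[chrom]
        pos = 0
        while True:
            start = pos + 1 + int(rng.exponential(mean_gap))
            glen = int(rng.uniform(0.5, 1.5) * cfg.mean_gene_length)
            end = start + max(glen, 50)
            if end >= L:
                break
            gid += 1
            intervals.append(
                GeneInterval(chrom, start, end,
                             "+" if rng.random() < 0.5 else "-",
                             f"gene{gid:05d}")
            )
            pos = end
    return GeneIntervals(intervals)


def spike_transcription_bias(
    genome: GenomeSequence, genes: GeneIntervals, cfg: SyntheticConfig,
    n_mutations: int = 200,
) -> MutationSet:
    """Motif mutations inside single-strand gene territory with a planted
    non-transcribed-strand fraction (``cfg.nontranscribed_fraction``)."""
    from .strandbias import _single_strand_territory

    rng = _stage_rng(cfg, "strandbias")
    motif = Motif(cfg.motif)
    alt = cfg.substitution.split(">")[1]
    nt_sites, t_sites = [], []
    for chrom, start, end, strand in _single_strand_territory(genes, genome):
        codes = _codes(genome[chrom][start:end])
        for pattern, centre_off, pyr_strand in (
            (motif.pattern, motif.offset_left, "+"),
            (motif.rc_pattern, motif.offset_right, "-"),
        ):
            if pattern == motif.rc_pattern and motif.rc_pattern == motif.pattern \
               and pyr_strand == "-":
                continue
            starts = np.flatnonzero(_pattern_starts(codes, pattern))
            for t in starts:
                pos0 = start + int(t) + centre_off
                target = nt_sites if pyr_strand == strand else t_sites
                target.append((chrom, pos0, pyr_strand))
    if not nt_sites or not t_sites:
        raise ValueError("no motif sites in single-strand gene territory")
    rng.shuffle(nt_sites)
    rng.shuffle(t_sites)
    n_nt = rng.binomial(n_mutations, cfg.nontranscribed_fraction)
    picks = nt_sites[:n_nt] + t_sites[: n_mutations - n_nt]
    if len(picks) < n_mutations:
        raise ValueError("not enough motif sites for requested mutations")
    records = []
    for k, (chrom, pos0, pyr_strand) in enumerate(picks):
        ref = genome[chrom][pos0]
        a = alt if pyr_strand == "+" else complement(alt)
        records.append(
            MutationRecord(f"iso{k % cfg.n_isolates + 1:03d}", chrom,
                           pos0 + 1, ref, a, vaf=0.95)
        )
    records.sort(key=lambda r: (r.chrom, r.pos, r.sample_id))
    return MutationSet(records,
                       provenance={"source": "synthetic spike_transcription_bias"})


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

@dataclass
class SimulationBundle:
    genome: GenomeSequence
    mutations: MutationSet
    genes: GeneIntervals
    manifest: dict


def simulate_cohort(cfg: SyntheticConfig, outdir=None) -> SimulationBundle:
    """Generate genome, SBS + indel/DBS/MBS catalog and genes; optionally
    write FASTA/VCF/TSV/BED and a JSON manifest of all planted parameters."""
    genome = generate_genome(cfg)
    sbs = spike_sbs(genome, cfg)
    indels = spike_indels_dbs(genome, cfg)
    genes = generate_genes(genome, cfg)
    seen = {(r.sample_id, *r.key) for r in sbs}
    extra = [r for r in indels if (r.sample_id, *r.key) not in seen]
    mutations = MutationSet(
        sorted(list(sbs) + extra, key=lambda r: (r.chrom, r.pos, r.sample_id)),
        provenance={"source": "synthetic cohort"},
    )
    manifest = {"config": asdict(cfg),
                "n_sbs": len(sbs), "n_other": len(extra),
                "n_genes": len(genes)}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, outdir / "genome.fa")
        write_mutations_tsv(mutations, outdir / "calls.tsv")
        write_mutations_vcf(mutations, outdir / "calls.vcf", genome)
        write_genes_bed(genes, outdir / "genes.bed")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return SimulationBundle(genome, mutations, genes, manifest)
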