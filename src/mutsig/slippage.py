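"""Templated-slippage classification of indels and tandem substitutions.

Translesion synthesis across a blocking adduct can slip and copy nearby
template: insertions then duplicate an adjacent tract (Rm→RMm — the
inserted base M equals the base m next to the reference base R), deletions
collapse single-letter runs, and double-/multi-base substitutions paste a
donor tract found within a few bp of the mutated positions.  This module
formalises those judgements into deterministic rules:

* insertion: templated (``dup_downstream``) if the inserted sequence equals
  the reference tract immediately following the insertion point,
  ``dup_upstream`` if it equals the tract immediately preceding it; when
  both match, downstream wins (+1 copying is the mechanistic expectation).
  Because VCF left-aligns indels, both the left-aligned and the maximally
  right-shifted placement are tested.
* deletion: ``run_deletion`` if the deleted tract is a single letter C or G
  lying within a maximal run of that letter of length >= ``run_min_len``.
* DBS/MBS: ``donor_templated`` if the alt tract occurs verbatim on the top
  strand within ±``donor_window`` bp, the donor not overlapping the mutated
  positions; the smallest |offset| wins, downstream preferred on ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import GenomeSequence, MutationRecord, MutationSet
from .spectrum import SubtelomereConfig, classify_location


@dataclass
class SlippageConfig:
    insertion_window: int = 20  # reported context, nt each side
    donor_window: int = 10      # DBS/MBS donor search, nt each side
    run_min_len: int = 3        # "a run of >2" C or G residues

    def __post_init__(self):
        if min(self.insertion_window, self.donor_window, self.run_min_len) < 1:
            raise ValueError("all SlippageConfig fields must be positive")


@dataclass
class SlippageCall:
    record: MutationRecord
    category: str  # dup_downstream | dup_upstream | donor_templated | run_deletion | untemplated
    templated: bool
    donor_offset: int | None = None
    copied_tract: str = ""
    context: str = ""
    note: str = ""


def _split_insertion(record: MutationRecord) -> tuple[int, str] | None:
    """Return (0-based anchor index, inserted sequence) for an anchor-style
    INS record (alt = ref + inserted).  None for complex representations."""
    if not record.alt.startswith(record.ref):
        return None
    inserted = record.alt[len(record.ref):]
    anchor = record.pos - 1 + len(record.ref) - 1
    return anchor, inserted


def _insertion_placements(seq: str, anchor: int, inserted: str):
    """Left-aligned placement plus the maximally right-shifted equivalent.

    Shifting an insertion right past a reference base requires that base to
    equal the first inserted base; the inserted string rotates accordingly.
    """
    placements = [(anchor, inserted)]
    a, ins = anchor, inserted
    while a + 1 < len(seq) and seq[a + 1] == ins[0]:
        a += 1
        ins = ins[1:] + ins[0]
    if (a, ins) != placements[0]:
        placements.append((a, ins))
    return placements


def detect_templated_insertion(
    record: MutationRecord, genome: GenomeSequence,
    cfg: SlippageConfig | None = None,
) -> SlippageCall:
    cfg = cfg or SlippageConfig()
    seq = genome[record.chrom]
    context = genome.context(record.chrom, record.pos, cfg.insertion_window)
    split = _split_insertion(record)
    if split is None:
        return SlippageCall(record, "untemplated", False, context=context,
                            note="complex insertion representation")
    anchor, inserted = split
    L = len(inserted)
    best: tuple[str, str] | None = None
    missing_flank = False
    for a, ins in _insertion_placements(seq, anchor, inserted):
        down = seq[a + 1 : a + 1 + L]
        up = seq[max(0, a - L + 1) : a + 1]
        if len(down) < L or len(up) < L:
            missing_flank = missing_flank or (len(down) < L)
        if len(down) == L and ins == down:
            best = ("dup_downstream", ins)
            break  # downstream wins outright
        if best is None and len(up) == L and ins == up:
            best = ("dup_upstream", ins)
    if best is not None:
        return SlippageCall(record, best[0], True, copied_tract=best[1],
                            context=context)
    note = "missing flank at chromosome end" if missing_flank else ""
    return SlippageCall(record, "untemplated", False, context=context, note=note)


def detect_templated_substitution(
    record: MutationRecord, genome: GenomeSequence,
    cfg: SlippageConfig | None = None,
) -> SlippageCall:
    """Donor search for DBS/MBS: alt tract present verbatim on the top
    strand within ±donor_window, donor disjoint from the mutated tract."""
    cfg = cfg or SlippageConfig()
    if len(record.ref) != len(record.alt) or len(record.ref) < 2:
        raise ValueError("detect_templated_substitution needs a DBS/MBS record")
    seq = genome[record.chrom]
    i0 = record.pos - 1
    L = len(record.ref)
    context = genome.context(record.chrom, record.pos, cfg.donor_window + L)
    candidates = []
    for d in range(-cfg.donor_window, cfg.donor_window + 1):
        if abs(d) < L:  # donor overlapping the mutated positions
            continue
        start = i0 + d
        if start < 0 or start + L > len(seq):
            continue
        if seq[start : start + L] == record.alt:
            candidates.append(d)
    if not candidates:
        return SlippageCall(record, "untemplated", False, context=context)
    # smallest |offset|; downstream (+) preferred on tie
    best = min(candidates, key=lambda d: (abs(d), 0 if d > 0 else 1))
    return SlippageCall(record, "donor_templated", True, donor_offset=best,
                        copied_tract=record.alt, context=context)


def classify_deletion(
    record: MutationRecord, genome: GenomeSequence,
    cfg: SlippageConfig | None = None,
) -> SlippageCall:
    cfg = cfg or SlippageConfig()
    seq = genome[record.chrom]
    context = genome.context(record.chrom, record.pos, cfg.insertion_window)
    if not record.ref.startswith(record.alt):
        return SlippageCall(record, "untemplated", False, context=context,
                            note="complex deletion representation")
    deleted = record.ref[len(record.alt):]
    start = record.pos - 1 + len(record.alt)  # 0-based first deleted base
    letters = set(deleted)
    if len(letters) != 1 or deleted[0] not in "CG":
        return SlippageCall(record, "untemplated", False, context=context)
    letter = deleted[0]
    run_start = start
    while run_start > 0 and seq[run_start - 1] == letter:
        run_start -= 1
    run_end = start + len(deleted)
    while run_end < len(seq) and seq[run_end] == letter:
        run_end += 1
    if run_end - run_start >= cfg.run_min_len:
        return SlippageCall(record, "run_deletion", True,
                            copied_tract=letter * (run_end - run_start),
                            context=context)
    return SlippageCall(record, "untemplated", False, context=context)


def classify_record(record: MutationRecord, genome: GenomeSequence,
                    cfg: SlippageConfig | None = None) -> SlippageCall:
    if record.mclass == "INS":
        return detect_templated_insertion(record, genome, cfg)
    if record.mclass == "DEL":
        return classify_deletion(record, genome, cfg)
    if record.mclass in ("DBS", "MBS"):
        return detect_templated_substitution(record, genome, cfg)
    raise ValueError(f"no slippage classification for class {record.mclass}")


def slippage_calls(mutations: MutationSet, genome: GenomeSequence,
                   cfg: SlippageConfig | None = None) -> list[SlippageCall]:
    """Classify every indel/DBS/MBS; deterministic in record order."""
    recs = sorted(mutations.of_class("INS", "DEL", "DBS", "MBS"),
                  key=lambda r: (r.chrom, r.pos, r.sample_id, r.ref, r.alt))
    return [classify_record(r, genome, cfg) for r in recs]


@dataclass
class IndelSummary:
    n_insertions: int
    n_deletions: int
    n_dbs: int
    n_mbs: int
    tract_length_hist: dict[int, int]
    inserted_base_composition: dict[str, int]
    cg_site_fraction: float
    templated_insertion_fraction: float
    run_deletion_fraction: float
    templated_dbs_fraction: float
    templated_mbs_fraction: float
    per_chromosome: dict[str, int]
    subtelomeric_fraction: float
    calls: list[SlippageCall] = field(default_factory=list)

    @property
    def insertion_proportion(self) -> float:
        n = self.n_insertions + self.n_deletions
        return self.n_insertions / n if n else float("nan")

    def to_frame(self):
        import pandas as pd

        rows = []
        for c in self.calls:
            r = c.record
            rows.append(
                dict(sample=r.sample_id, chrom=r.chrom, pos=r.pos, ref=r.ref,
                     alt=r.alt, mclass=r.mclass, category=c.category,
                     templated=c.templated, donor_offset=c.donor_offset,
                     copied_tract=c.copied_tract, context=c.context)
            )
        return pd.DataFrame(rows)


def _frac(num: int, den: int) -> float:
    return num / den if den else float("nan")


def indel_summary(
    mutations: MutationSet, genome: GenomeSequence,
    cfg: SlippageConfig | None = None,
    subtel: SubtelomereConfig | None = None,
) -> IndelSummary:
    """Aggregate slippage classifications into the headline indel table:
    insertion/deletion split, tract lengths, inserted-base composition,
    fraction of insertions at C/G sites (anchor or following base C/G),
    templated fractions and location breakdowns."""
    cfg = cfg or SlippageConfig()
    subtel = subtel or SubtelomereConfig()
    calls = slippage_calls(mutations, genome, cfg)
    tract_hist: dict[int, int] = {}
    inserted_comp: dict[str, int] = {}
    per_chrom: dict[str, int] = {}
    n_ins = n_del = n_dbs = n_mbs = 0
    ins_templated = ins_cg = 0
    del_run = 0
    dbs_templated = mbs_templated = 0
    n_subtel = 0
    for c in calls:
        r = c.record
        per_chrom[r.chrom] = per_chrom.get(r.chrom, 0) + 1
        region, _ = classify_location(r, genome, subtel)
        if region == "subtelomeric":
            n_subtel += 1
        if r.mclass == "INS":
            n_ins += 1
            inserted = r.alt[len(r.ref):] if r.alt.startswith(r.ref) else r.alt
            tract_hist[len(inserted)] = tract_hist.get(len(inserted), 0) + 1
            for b in inserted:
                inserted_comp[b] = inserted_comp.get(b, 0) + 1
            seq = genome[r.chrom]
            anchor = r.pos - 1 + len(r.ref) - 1
            nxt = seq[anchor + 1] if anchor + 1 < len(seq) else ""
            if seq[anchor] in "CG" or nxt in "CG":
                ins_cg += 1
            if c.templated:
                ins_templated += 1
        elif r.mclass == "DEL":
            n_del += 1
            deleted = r.ref[len(r.alt):] if r.ref.startswith(r.alt) else r.ref
            tract_hist[len(deleted)] = tract_hist.get(len(deleted), 0) + 1
            if c.category == "run_deletion":
                del_run += 1
        elif r.mclass == "DBS":
            n_dbs += 1
            if c.templated:
                dbs_templated += 1
        elif r.mclass == "MBS":
            n_mbs += 1
            if c.templated:
                mbs_templated += 1
    return IndelSummary(
        n_insertions=n_ins,
        n_deletions=n_del,
        n_dbs=n_dbs,
        n_mbs=n_mbs,
        tract_length_hist=dict(sorted(tract_hist.items())),
        inserted_base_composition=dict(sorted(inserted_comp.items())),
        cg_site_fraction=_frac(ins_cg, n_ins),
        templated_insertion_fraction=_frac(ins_templated, n_ins),
        run_deletion_fraction=_frac(del_run, n_del),
        templated_dbs_fraction=_frac(dbs_templated, n_dbs),
        templated_mbs_fraction=_frac(mbs_templated, n_mbs),
        per_chromosome=dict(sorted(per_chrom.items())),
        subtelomeric_fraction=_frac(n_subtel, len(calls)),
        calls=calls,
    )
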