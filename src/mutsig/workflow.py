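"""End-to-end orchestration: ingest → spectrum → enrichment → logo →
slippage → strand bias, with a single JSON report and fixed-precision TSV
outputs so reruns on identical inputs diff byte-identically."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import io as mio
from .enrichment import TrinucleotideEnrichment
from .logo import MutationLogo
from .slippage import SlippageConfig, indel_summary
from .spectrum import (SubtelomereConfig, classify_location, mutation_density,
                       mutations_per_isolate, spectrum_table,
                       strand_resolved_spectrum, subtelomeric_territory)
from .strandbias import TranscriptionStrandBias

log = logging.getLogger("mutsig.workflow")

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    genome: str
    calls: str
    out_dir: str
    calls_format: str = "tsv"
    parent: str | None = None
    genes: str | None = None
    min_vaf: float = 0.90
    drop_cross_sample_duplicates: bool = False
    subtel_bp: int = 30_000
    motifs: list = field(default_factory=lambda: ["cCg:C>G", "nCg:C>G"])
    window_radius: int = 20
    alpha: float = 0.05
    correction: str = "bonferroni"
    per_sample: bool = False
    flank_k: int = 2
    donor_window: int = 10
    strand_bias: bool = False
    strand_bias_expected: str = "fifty_fifty"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if isinstance(raw.get("motifs"), str):
            raw["motifs"] = [m.strip() for m in raw["motifs"].split(",")]
        return cls(**raw)


def _parse_motifs(specs: list) -> list[tuple[str, str]]:
    out = []
    for s in specs:
        motif, _, subst = s.partition(":")
        out.append((motif, subst or "C>G"))
    return out


def _write_tsv(frame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("[%s] starting", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every requested stage, write per-stage TSVs plus ``report.json``
    under ``cfg.out_dir`` and return the report dict."""
    logging.basicConfig(stream=sys.stderr, level=cfg.log_level,
                        format="%(name)s: %(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in vars(cfg).items()}}

    if cfg.strand_bias and not cfg.genes:
        raise RuntimeError("stage 'strand_bias' failed: no genes file supplied")

    genome = _stage("ingest")(mio.load_fasta)(cfg.genome)
    ingest = mio.IngestConfig(
        min_vaf=cfg.min_vaf,
        drop_cross_sample_duplicates=cfg.drop_cross_sample_duplicates)
    mutations = _stage("ingest")(mio.load_mutations)(
        cfg.calls, cfg.calls_format, ingest, genome)
    log.info("[ingest] %d calls from %s", len(mutations), cfg.calls)
    if cfg.parent:
        parent = _stage("ingest")(mio.load_mutations)(
            cfg.parent, cfg.calls_format, mio.IngestConfig(min_vaf=0.0), genome)
        mutations = mio.subtract_parental(
            mutations, parent, cfg.drop_cross_sample_duplicates)
        log.info("[ingest] %d calls after parental subtraction", len(mutations))

    subtel = SubtelomereConfig(cfg.subtel_bp)

    @_stage("spectrum")
    def _spectrum():
        table = spectrum_table(mutations, genome)
        _write_tsv(table.to_frame(), out / "spectrum_classes.tsv")
        _write_tsv(table.channels_frame(), out / "spectrum_channels.tsv")
        sub = mutations.filter(
            lambda r: classify_location(r, genome, subtel)[0] == "subtelomeric")
        strand = strand_resolved_spectrum(sub, genome, subtel)
        _write_tsv(strand.to_frame(), out / "spectrum_strand_aware.tsv")
        counts, median = mutations_per_isolate(mutations.of_class("SBS"))
        n_iso = max(len(counts), 1)
        territory = subtelomeric_territory(genome, subtel)
        dens = mutation_density(sub, genome, territory, n_iso)
        n_sbs = len(mutations.of_class("SBS"))
        n_sub = len(sub.of_class("SBS"))
        return {
            "n_sbs": n_sbs,
            "n_subtelomeric_sbs": n_sub,
            "subtelomeric_percent": 100.0 * n_sub / n_sbs if n_sbs else 0.0,
            "median_sbs_per_isolate": median,
            "ssdna_territory_bp": territory,
            "density_per_isolate_per_bp": dens,
            "class_counts": table.classes,
        }

    report["spectrum"] = _spectrum()

    @_stage("enrichment")
    def _enrichment():
        model = TrinucleotideEnrichment(
            mutations, genome, motifs=_parse_motifs(cfg.motifs),
            window_radius=cfg.window_radius, alpha=cfg.alpha,
            correction=cfg.correction)
        res = model.fit(per_sample=cfg.per_sample)
        _write_tsv(res.to_frame(), out / "enrichment.tsv")
        return [
            dict(motif=r.motif, substitution=r.substitution,
                 sample=r.sample_id, enrichment=r.enrichment,
                 p_value=r.p_value, corrected_p=r.corrected_p,
                 min_load=r.min_load)
            for r in res
        ]

    report["enrichment"] = _enrichment()

    @_stage("logo")
    def _logo():
        substitutions = sorted({s for _, s in _parse_motifs(cfg.motifs)})
        rows = {}
        for subst in substitutions:
            model = MutationLogo(mutations, genome, substitution=subst,
                                 flank_k=cfg.flank_k, alpha=cfg.alpha)
            if len(model.fg) == 0 or len(model.bg) == 0:
                log.info("[logo] skipping %s (empty fg or bg)", subst)
                continue
            res = model.fit()
            _write_tsv(res.to_frame(),
                       out / f"logo_{subst.replace('>', '_')}.tsv")
            rows[subst] = {
                "n_fg": res.n_fg, "n_bg": res.n_bg,
                "significant": [
                    [c.position, c.base, round(c.height, 4)]
                    for c in res.significant_cells()
                ],
            }
        return rows

    report["logo"] = _logo()

    @_stage("slippage")
    def _slippage():
        summary = indel_summary(
            mutations, genome, SlippageConfig(donor_window=cfg.donor_window),
            subtel)
        _write_tsv(summary.to_frame(), out / "slippage.tsv")
        return {
            "n_insertions": summary.n_insertions,
            "n_deletions": summary.n_deletions,
            "n_dbs": summary.n_dbs,
            "n_mbs": summary.n_mbs,
            "templated_insertion_fraction":
                summary.templated_insertion_fraction,
            "run_deletion_fraction": summary.run_deletion_fraction,
            "templated_dbs_fraction": summary.templated_dbs_fraction,
            "templated_mbs_fraction": summary.templated_mbs_fraction,
            "cg_site_fraction": summary.cg_site_fraction,
        }

    report["slippage"] = _slippage()

    if cfg.strand_bias:
        @_stage("strand_bias")
        def _bias():
            genes = mio.load_gene_annotation(
                cfg.genes, "gff3" if str(cfg.genes).endswith(
                    (".gff", ".gff3")) else "bed6")
            motif, subst = _parse_motifs(cfg.motifs)[0]
            model = TranscriptionStrandBias(
                mutations, genes, genome, motif=motif, substitution=subst,
                expected=cfg.strand_bias_expected)
            res = model.fit()
            _write_tsv(res.to_frame(), out / "strand_bias.tsv")
            r = res.single
            return dict(n_transcribed=r.n_transcribed,
                        n_nontranscribed=r.n_nontranscribed,
                        n_excluded=r.n_excluded, chi2=r.chi2,
                        p_value=r.p_value)

        report["strand_bias"] = _bias()

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    log.info("report written to %s", out / "report.json")
    return report
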