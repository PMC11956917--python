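"""Position-specific flank composition logos around mutated bases.

For one substitution class (the foreground, e.g. all C→G in pyrimidine
space) versus all other substitutions of the same reference base (the
background), each flank position in ``−k..+k`` (position 0, the mutated
base, excluded) is scored per base with an exact binomial test: the
foreground count k out of n against the background proportion.  Two
one-sided tails are computed and the smaller taken; the signed height is
``−log10(corrected p)``, positive for over-representation.  Bonferroni
correction runs over all (position, base) pairs.

This is an exact-binomial statistic in the spirit of probability logos; it
is a documented approximation, not a port of any hosted web tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._seq import BASES, PURINES, revcomp
from .io import GenomeSequence, MutationSet


@dataclass
class LogoConfig:
    """``flank_k`` positions each side (default 2: pentanucleotide context);
    Bonferroni over the 2k × 4 (position, base) tests."""

    flank_k: int = 2
    alpha: float = 0.05
    correction: str = "bonferroni"

    def __post_init__(self):
        if self.flank_k < 1:
            raise ValueError("flank_k must be >= 1")


@dataclass
class LogoCell:
    position: int
    base: str
    fg_count: int
    fg_n: int
    bg_count: int
    bg_n: int
    p_value: float
    corrected_p: float
    height: float
    significant: bool


def _pyrimidine_window(genome: GenomeSequence, record, k: int) -> list[str | None]:
    """Flank bases at offsets −k..+k in pyrimidine orientation; positions
    outside the chromosome are None (truncated windows drop only the missing
    positions).  Index k is the mutated base itself."""
    seq = genome[record.chrom]
    i = record.pos - 1
    raw = [
        seq[i + off] if 0 <= i + off < len(seq) else None
        for off in range(-k, k + 1)
    ]
    if record.ref in PURINES:
        raw = [None if b is None else revcomp(b) for b in raw[::-1]]
    return raw


def flank_profiles(
    fg: MutationSet, bg: MutationSet, genome: GenomeSequence,
    cfg: LogoConfig | None = None,
) -> dict:
    """Per-position base-count matrices for foreground and background.

    Both sets must be SBS; flanks are pyrimidine-normalized together with
    the mutation.  Returns ``{"fg": {pos: {base: n}}, "bg": ...}`` over
    positions −k..+k excluding 0.
    """
    cfg = cfg or LogoConfig()
    if len(fg.of_class("SBS")) == 0:
        raise ValueError("foreground set is empty")
    out = {}
    for name, mset in (("fg", fg), ("bg", bg)):
        counts = {
            pos: {b: 0 for b in BASES}
            for pos in range(-cfg.flank_k, cfg.flank_k + 1)
            if pos != 0
        }
        for r in mset.of_class("SBS"):
            window = _pyrimidine_window(genome, r, cfg.flank_k)
            for j, base in enumerate(window):
                pos = j - cfg.flank_k
                if pos == 0 or base is None or base not in BASES:
                    continue
                counts[pos][base] += 1
        out[name] = counts
    return out


def logo_significance(profiles: dict, cfg: LogoConfig | None = None) -> "LogoResults":
    """Score every (position, base) cell of the profiles.

    The background proportion at a position is that base's background count
    over the background total there; cells are Bonferroni-corrected over the
    whole (position, base) family.  Raises when the background is empty.
    """
    cfg = cfg or LogoConfig()
    fg, bg = profiles["fg"], profiles["bg"]
    positions = sorted(fg)
    if all(sum(bg[p].values()) == 0 for p in positions):
        raise ValueError("background profile is empty")
    family = len(positions) * len(BASES)
    tiny = np.finfo(float).tiny
    cells: list[LogoCell] = []
    for pos in positions:
        fg_n = sum(fg[pos].values())
        bg_n = sum(bg[pos].values())
        for base in BASES:
            k = fg[pos][base]
            bk = bg[pos][base]
            if fg_n == 0 or bg_n == 0:
                p = 1.0
                sign = 0.0
            else:
                phat = bk / bg_n
                p_greater = stats.binomtest(k, fg_n, phat,
                                            alternative="greater").pvalue
                p_less = stats.binomtest(k, fg_n, phat,
                                         alternative="less").pvalue
                p = float(min(p_greater, p_less))
                sign = 1.0 if (k / fg_n) > phat else -1.0
                if np.isclose(k / fg_n, phat):
                    sign = 0.0
            corrected = min(1.0, p * family)
            height = sign * (-np.log10(max(corrected, tiny)))
            cells.append(
                LogoCell(position=pos, base=base, fg_count=k, fg_n=fg_n,
                         bg_count=bk, bg_n=bg_n, p_value=p,
                         corrected_p=corrected, height=float(height),
                         significant=corrected <= cfg.alpha)
            )
    n_fg = max((c.fg_n for c in cells), default=0)
    n_bg = max((c.bg_n for c in cells), default=0)
    return LogoResults(model=None, cells=cells, n_fg=n_fg, n_bg=n_bg, config=cfg)


class MutationLogo:
    """Flank-composition logo model for one substitution class.

    Foreground = SBS of ``substitution`` (pyrimidine space); background =
    all other substitutions of the same reference pyrimidine, following the
    convention that the null flank distribution is taken from mutations of
    other types rather than genomic composition.
    """

    def __init__(self, mutations: MutationSet, genome: GenomeSequence,
                 substitution: str = "C>G", flank_k: int = 2,
                 alpha: float = 0.05):
        from ._seq import pyrimidine_class

        self.mutations = mutations
        self.genome = genome
        self.substitution = substitution
        self.config = LogoConfig(flank_k=flank_k, alpha=alpha)
        base = substitution.split(">")[0]
        sbs = mutations.of_class("SBS")
        self.fg = sbs.filter(
            lambda r: pyrimidine_class(r.ref, r.alt) == substitution)
        self.bg = sbs.filter(
            lambda r: pyrimidine_class(r.ref, r.alt) != substitution
            and pyrimidine_class(r.ref, r.alt).startswith(base))

    def fit(self) -> "LogoResults":
        profiles = flank_profiles(self.fg, self.bg, self.genome, self.config)
        results = logo_significance(profiles, self.config)
        results.model = self
        return results


@dataclass
class LogoResults:
    model: MutationLogo | None
    cells: list[LogoCell]
    n_fg: int
    n_bg: int
    config: LogoConfig = field(default_factory=LogoConfig)

    def __iter__(self):
        return iter(self.cells)

    def cell(self, position: int, base: str) -> LogoCell:
        for c in self.cells:
            if c.position == position and c.base == base:
                return c
        raise KeyError((position, base))

    def significant_cells(self) -> list[LogoCell]:
        return [c for c in self.cells if c.significant]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                dict(position=c.position, base=c.base, fg_count=c.fg_count,
                     fg_n=c.fg_n, bg_count=c.bg_count, bg_n=c.bg_n,
                     p_value=c.p_value, corrected_p=c.corrected_p,
                     height=c.height, significant=c.significant)
                for c in self.cells
            ]
        )

    def summary(self) -> str:
        lines = [
            f"Flank logo  N(fg)={self.n_fg}  N(bg)={self.n_bg}",
            "=" * 64,
            f"{'pos':>4} {'base':>4} {'fg':>6} {'bg':>6} {'height':>9} {'sig':>4}",
            "-" * 64,
        ]
        for c in self.cells:
            lines.append(
                f"{c.position:>4} {c.base:>4} {c.fg_count:>6} {c.bg_count:>6} "
                f"{c.height:>9.2f} {'*' if c.significant else '':>4}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot(self, ax=None):  # pragma: no cover - convenience only
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        positions = sorted({c.position for c in self.cells})
        width = 0.2
        for bi, base in enumerate(BASES):
            hs = [self.cell(p, base).height for p in positions]
            ax.bar([p + (bi - 1.5) * width for p in positions], hs,
                   width=width, label=base)
        ax.axhline(0, color="k", lw=0.8)
        ax.set_xlabel("flank position")
        ax.set_ylabel("signed -log10 corrected p")
        ax.legend()
        return ax
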