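"""Low-level nucleotide-sequence helpers shared across modules.

Conventions used throughout the package:

* genome sequences are uppercase strings over ``{A, C, G, T, N}``;
* positions in :class:`~mutsig.io.MutationRecord` are 1-based (VCF style),
  internal string indices are 0-based;
* "pyrimidine space" means every substitution and its local context are
  reported with the pyrimidine (C or T) as the mutated base, reverse
  complementing purine-centred calls.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
BASES = "ACGT"

#: the six pyrimidine substitution classes, in conventional plot order
PYR_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: all twelve top-strand substitution classes (no pyrimidine collapsing)
TOP_STRAND_CLASSES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)


def revcomp(seq: str) -> str:
    """Reverse complement of *seq* (N maps to N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def pyrimidine_class(ref: str, alt: str) -> str:
    """Collapse a single-base substitution into pyrimidine space.

    ``("G", "C") -> "C>G"`` because a G>C on the top strand is a C>G on the
    bottom strand.
    """
    if ref in PURINES:
        ref, alt = complement(ref), complement(alt)
    return f"{ref}>{alt}"


def normalize_substitution(ref: str, alt: str, context: str) -> tuple[str, str]:
    """Pyrimidine-normalize a substitution and its top-strand context.

    *context* is the top-strand window centred on the mutated base (any odd
    length).  If the reference base is a purine both the substitution and the
    context are reverse complemented, so e.g. ``(G>C, "CGG")`` becomes
    ``(C>G, "CCG")``.
    """
    if len(context) % 2 != 1:
        raise ValueError("context must have odd length (centred on the mutated base)")
    if ref in PURINES:
        return f"{complement(ref)}>{complement(alt)}", revcomp(context)
    return f"{ref}>{alt}", context


class Motif:
    """A mutation motif such as ``cCg``: lowercase fixed flanks, exactly one
    uppercase mutated pyrimidine, ``n``/``N`` matching any unambiguous base.

    ``offset_left``/``offset_right`` give the number of motif positions on
    each side of the mutated base.  ``top_patterns()`` returns the pattern and
    its reverse complement as uppercase strings (with ``N`` wildcards) for
    scanning the top strand of the genome; the mutated base sits at index
    ``offset_left`` in the forward pattern and ``offset_right`` in the
    reverse-complement pattern.
    """

    def __init__(self, text: str):
        uppers = [i for i, c in enumerate(text) if c.isupper() and c != "N"]
        if len(uppers) != 1:
            raise ValueError(
                f"motif {text!r} must contain exactly one uppercase mutated base"
            )
        self.text = text
        self.center = uppers[0]
        self.base = text[self.center]
        if self.base not in PYRIMIDINES:
            raise ValueError(
                f"motif {text!r}: mutated base must be a pyrimidine (C or T)"
            )
        pat = text.upper()
        if any(c not in "ACGTN" for c in pat):
            raise ValueError(f"motif {text!r}: invalid characters")
        self.pattern = pat
        self.rc_pattern = revcomp(pat)
        self.offset_left = self.center
        self.offset_right = len(text) - self.center - 1

    def __len__(self) -> int:
        return len(self.text)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Motif({self.text!r})"

    def matches_context(self, pyr_context: str) -> bool:
        """Does a pyrimidine-normalized context (odd length, centred on the
        mutated base) match the motif?  ``n`` matches A/C/G/T but never N."""
        k = len(pyr_context) // 2
        if self.offset_left > k or self.offset_right > k:
            raise ValueError("context narrower than motif")
        window = pyr_context[k - self.offset_left : k + self.offset_right + 1]
        return _pattern_match(window, self.pattern)


def _pattern_match(seq: str, pattern: str) -> bool:
    if len(seq) != len(pattern):
        return False
    for s, p in zip(seq, pattern):
        if p == "N":
            if s not in BASES:
                return False
        elif s != p:
            return False
    return True


def count_pattern(seq: str, pattern: str) -> int:
    """Overlapping occurrences of *pattern* in *seq*.  ``N`` in the pattern
    matches any of A/C/G/T; ``N`` in *seq* never matches anything."""
    n, m = len(seq), len(pattern)
    return sum(_pattern_match(seq[i : i + m], pattern) for i in range(n - m + 1))


def count_motif_occurrences(seq: str, motif: Motif) -> int:
    """Occurrences of the motif in pyrimidine space on the top strand of
    *seq*: forward pattern plus its reverse complement (counted once when the
    pattern is its own reverse complement)."""
    total = count_pattern(seq, motif.pattern)
    if motif.rc_pattern != motif.pattern:
        total += count_pattern(seq, motif.rc_pattern)
    return total
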