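"""Small shared helpers used across modules."""

from __future__ import annotations

import math

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string, preserving case and Ns."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Case-insensitive G+C fraction of a sequence."""
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def lowercase_fraction(seq: str) -> float:
    """Fraction of soft-masked (lowercase) residues."""
    if not seq:
        return 0.0
    return sum(c.islower() for c in seq) / len(seq)


def completeness_threshold(fraction: float, n_taxa: int) -> int:
    """Minimum taxon count implied by a completeness fraction.

    ``ceil(fraction * n_taxa)``, guarded against binary-float artifacts so
    that e.g. 0.70 x 14 -> 10 and 0.75 x 44 -> 33 hold exactly.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"completeness fraction must be in (0, 1], got {fraction}")
    return math.ceil(round(fraction * n_taxa, 9))
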