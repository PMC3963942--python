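"""Gapless primer-binding-site search with mismatches.

Primer/NUMT cross-matching is deliberately modelled as an exhaustive
IUPAC-aware Hamming scan rather than a heuristic local alignment: NUMT
integrations are co-linear with modern mtDNA over primer-length windows, so
a gapless scan with a small mismatch budget captures exactly the match
categories used for co-amplification risk assessment (perfect match, one
mismatch, two or more mismatches) without alignment-score tuning.

Positions are 1-based.  A hit's ``start`` is the template position of the
primer's 5' end in plus-strand coordinates: the left end of the matched
window for plus-strand hits, the right end for minus-strand hits.  This
makes a PCR product run from forward-hit start to reverse-hit start,
inclusive, on the plus strand.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .catalog import IUPAC_BITS, Primer, SequenceRecord, revcomp

logger = logging.getLogger(__name__)

#: Default mismatch budget: 20 % of a 20-mer.  Large enough to populate the
#: "two or more mismatches" category, small enough to keep scans specific.
DEFAULT_MAX_MISMATCHES = 4

_BIT_LUT = np.zeros(256, dtype=np.uint8)
for _base, _bits in IUPAC_BITS.items():
    _BIT_LUT[ord(_base)] = _bits


def encode_bits(seq: str) -> np.ndarray:
    """Encode an IUPAC string as per-base bit sets (A=1, C=2, G=4, T=8)."""
    return _BIT_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class MatchCondition(Enum):
    """Per-primer match category by mismatch count: 0 / 1 / >=2."""

    PERFECT = 0
    ONE_MISMATCH = 1
    MULTI_MISMATCH = 2


class PairMatchClass(Enum):
    """Unordered combination of the two primers' match conditions.

    The six symbols follow the published screening-table legend:
    ``⊚`` both perfect; ``△`` perfect + one mismatch; ``▴`` one mismatch
    each; ``▽`` perfect + two-or-more; ``▾`` one + two-or-more; ``#``
    two-or-more for both.
    """

    BOTH_PERFECT = "⊚"
    PERFECT_ONE = "△"
    BOTH_ONE = "▴"
    PERFECT_MULTI = "▽"
    ONE_MULTI = "▾"
    BOTH_MULTI = "#"

    @property
    def symbol(self) -> str:
        return self.value


_PAIR_TABLE = {
    (MatchCondition.PERFECT, MatchCondition.PERFECT): PairMatchClass.BOTH_PERFECT,
    (MatchCondition.PERFECT, MatchCondition.ONE_MISMATCH): PairMatchClass.PERFECT_ONE,
    (MatchCondition.ONE_MISMATCH, MatchCondition.ONE_MISMATCH): PairMatchClass.BOTH_ONE,
    (MatchCondition.PERFECT, MatchCondition.MULTI_MISMATCH): PairMatchClass.PERFECT_MULTI,
    (MatchCondition.ONE_MISMATCH, MatchCondition.MULTI_MISMATCH): PairMatchClass.ONE_MULTI,
    (MatchCondition.MULTI_MISMATCH, MatchCondition.MULTI_MISMATCH): PairMatchClass.BOTH_MULTI,
}


@dataclass(frozen=True)
class PrimerHit:
    """One gapless binding site of a primer on a template."""

    template_id: str
    primer_name: str
    strand: str  # "plus" | "minus"
    start: int  # template position of the primer's 5' end (plus-strand coords)
    length: int
    mismatches: int
    three_prime_terminal_match: bool

    def window(self, template_length: int) -> tuple[int, int]:
        """Leftmost/rightmost plus-strand positions covered by the hit.

        May wrap the origin on circular templates (left > right).
        """
        def w(p: int) -> int:
            return (p - 1) % template_length + 1

        if self.strand == "plus":
            return self.start, w(self.start + self.length - 1)
        return w(self.start - self.length + 1), self.start


def classify_match(hit: PrimerHit | int) -> MatchCondition:
    """Map a hit (or raw mismatch count) to its match category."""
    m = hit if isinstance(hit, int) else hit.mismatches
    if m < 0:
        raise ValueError(f"negative mismatch count: {m}")
    if m == 0:
        return MatchCondition.PERFECT
    if m == 1:
        return MatchCondition.ONE_MISMATCH
    return MatchCondition.MULTI_MISMATCH


def classify_pair(a: MatchCondition, b: MatchCondition) -> PairMatchClass:
    """Symbol for an unordered pair of match conditions (symmetric)."""
    key = tuple(sorted((a, b), key=lambda c: c.value))
    return _PAIR_TABLE[key]  # type: ignore[index]


def _window_mismatches(template_bits: np.ndarray, primer_bits: np.ndarray,
                       n_windows: int) -> np.ndarray:
    """Mismatch count of every length-m window start in 0..n_windows-1."""
    m = primer_bits.size
    windows = np.lib.stride_tricks.sliding_window_view(template_bits, m)[:n_windows]
    compat = (windows & primer_bits[np.newaxis, :]) != 0
    return (m - compat.sum(axis=1)).astype(np.int64)


def scan_primer(
    primer: Primer,
    template: SequenceRecord,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    *,
    template_n_matches: bool = True,
) -> list[PrimerHit]:
    """Every gapless binding site of ``primer`` on both template strands.

    A position matches when the IUPAC code sets of the two bases intersect;
    ``N`` in the template matches everything unless ``template_n_matches``
    is False, in which case template Ns count as mismatches against any
    primer base.  Circular templates are scanned across the origin exactly
    once.  Hits are sorted by (strand, start).
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    m = len(primer.sequence)
    n = len(template.sequence)
    if m > n:
        logger.warning(
            "primer %s (%d nt) longer than template %s (%d nt); no scan",
            primer.name, m, template.id, n,
        )
        return []

    tbits = encode_bits(template.sequence)
    if not template_n_matches:
        tbits = tbits.copy()
        tbits[np.frombuffer(template.sequence.encode(), dtype=np.uint8) == ord("N")] = 0
    if template.circular:
        tbits = np.concatenate([tbits, tbits[: m - 1]])
        n_windows = n
    else:
        n_windows = n - m + 1

    hits: list[PrimerHit] = []
    pbits_plus = encode_bits(primer.sequence)
    pbits_minus = encode_bits(revcomp(primer.sequence))
    for strand, pbits in (("plus", pbits_plus), ("minus", pbits_minus)):
        mism = _window_mismatches(tbits, pbits, n_windows)
        for left0 in np.flatnonzero(mism <= max_mismatches):
            left = int(left0)
            right = left + m - 1  # index into extended array
            if strand == "plus":
                start = left + 1
                # 3'-terminal base of the primer sits at the window's right end
                terminal = bool(tbits[right] & pbits[-1])
            else:
                start = right % n + 1
                # on the minus strand the primer's 3' end maps to the left end
                terminal = bool(tbits[left] & pbits[0])
            hits.append(
                PrimerHit(
                    template_id=template.id,
                    primer_name=primer.name,
                    strand=strand,
                    start=start,
                    length=m,
                    mismatches=int(mism[left]),
                    three_prime_terminal_match=terminal,
                )
            )
    hits.sort(key=lambda h: (h.strand, h.start))
    return hits


def hits_to_rows(hits: list[PrimerHit]) -> list[dict]:
    """Flatten hits for a TSV report."""
    return [
        {
            "template_id": h.template_id,
            "strand": h.strand,
            "start": h.start,
            "primer_name": h.primer_name,
            "mismatches": h.mismatches,
            "category": classify_match(h).name,
        }
        for h in hits
    ]
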