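"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written position-by-position in plain Python, without
reusing the package's encodings, so that agreement with the vectorised
scanner or the closed-form duplex model is a genuine two-route check.
"""
from __future__ import annotations

import random

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def naive_scan(primer: str, template: str, max_mismatches: int,
               circular: bool = False) -> set[tuple[str, int, int]]:
    """All (strand, 5'-end position, mismatches) binding sites.

    Position-by-position Hamming comparison with IUPAC set intersection;
    circular templates are extended by one primer length minus one and
    window starts limited to the original length.
    """
    n, m = len(template), len(primer)
    if m > n:
        return set()
    ext = template + (template[: m - 1] if circular else "")
    n_windows = n if circular else n - m + 1
    hits = set()
    for strand, probe in (("plus", primer), ("minus", naive_revcomp(primer))):
        for i in range(n_windows):
            window = ext[i : i + m]
            mm = sum(
                1 for a, b in zip(probe, window)
                if not (IUPAC_SETS[a] & IUPAC_SETS[b])
            )
            if mm <= max_mismatches:
                start = i + 1 if strand == "plus" else (i + m - 1) % n + 1
                hits.add((strand, start, mm))
    return hits


def naive_fragments(amplicon_length: int, offsets: list[int]) -> list[int]:
    """Cleavage intervals by direct enumeration of surviving positions.

    Each mismatch offset is excised; runs of consecutive surviving offsets
    are fragments.  Zero-length runs between adjacent mismatches are kept
    as size-0 entries to preserve the k+1 fragment count.
    """
    cut = set(offsets)
    boundaries = [0] + sorted(cut) + [amplicon_length + 1]
    return [b - a - 1 for a, b in zip(boundaries, boundaries[1:])]


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def mutate_positions(rng: random.Random, seq: str, k: int) -> str:
    """Substitute exactly k distinct random positions."""
    positions = rng.sample(range(len(seq)), k)
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)
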