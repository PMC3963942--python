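"""Heteroduplex annealing, mismatch-nuclease fragments, interference calls.

Model summary
-------------
A PCR product amplified from a mixed template population (heteroplasmic
mtDNA, or mtDNA plus a co-amplified nuclear insertion) is denatured and
reannealed.  Under random (mass-action) reannealing, strands pair in
proportion to allele fractions: alleles i and j form duplexes with
abundance ``f_i * f_j`` per ordered pair, so a biallelic mixture with minor
fraction f yields total heteroduplex abundance ``2 f (1 - f)``.

A CEL-family mismatch endonuclease nicks both strands on the 3' side of
every mismatched base, so a heteroduplex with k mismatches falls apart into
k + 1 double-stranded fragments.  The cut convention is calibrated on the
worked single-mismatch case: an amplicon spanning positions s..e with one
mismatch at p yields fragments of ``p - s`` and ``e - p`` bp (the mismatched
base itself is lost to the staggered nicks), hence for k mismatches the
fragment sizes sum to ``(e - s + 1) - k``.

Fragments are then read out as a size-based chromatogram: abundances are
mass fractions (a fragment inherits its parent duplex's abundance scaled by
its share of the parent's length, so total signal is conserved), peaks
within sizing resolution are merged, and peaks below a detectability floor
(default 100 bp) are dropped.  NUMT interference is called by comparing the
peak profile of a total-DNA amplification against that of pure mtDNA.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import Region, region_length

#: Smallest fragment reliably detected by the size-based readout, in bp.
DEFAULT_MIN_DETECTABLE_SIZE = 100

#: Heteroduplex abundance at the ~5 % minor-fraction detection floor of the
#: denaturing-HPLC readout: 2 * 0.05 * 0.95.
DHPLC_MIN_HET_FRACTION = 2 * 0.05 * 0.95

#: Abundance (mass-fraction) below which a peak difference is noise.
DEFAULT_ABUNDANCE_TOLERANCE = 0.01

_FRACTION_ATOL = 1e-9


class UnsupportedMixtureError(ValueError):
    """Raised for mixtures the v1 equal-length gapless model cannot handle."""


@dataclass
class TemplateMixture:
    """Alleles of one amplicon with their template fractions.

    All alleles must be the same length (gapless alignment); fractions must
    be non-negative and sum to 1.
    """

    alleles: list[str]
    fractions: list[float]
    names: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.fractions) or not self.alleles:
            raise ValueError("need one fraction per allele")
        lengths = {len(a) for a in self.alleles}
        if len(lengths) != 1:
            raise UnsupportedMixtureError(
                f"alleles of unequal length {sorted(lengths)}: the gapless "
                "equal-length duplex model cannot align them"
            )
        if any(f < 0 for f in self.fractions):
            raise ValueError("negative allele fraction")
        if abs(sum(self.fractions) - 1.0) > _FRACTION_ATOL:
            raise ValueError(f"fractions sum to {sum(self.fractions)}, not 1")
        if self.names is None:
            self.names = [f"allele{i}" for i in range(len(self.alleles))]

    @property
    def amplicon_length(self) -> int:
        return len(self.alleles[0])


@dataclass(frozen=True)
class DuplexSpecies:
    """An annealed strand pair from two (possibly identical) alleles."""

    strand_a: int
    strand_b: int
    mismatch_offsets: tuple[int, ...]  # 1-based offsets within the amplicon
    abundance: float

    @property
    def is_heteroduplex(self) -> bool:
        """Carries at least one mismatched base pair (cleavable)."""
        return len(self.mismatch_offsets) > 0


def anneal(mixture: TemplateMixture) -> list[DuplexSpecies]:
    """Duplex species under random reannealing of a template mixture.

    Ordered strand pairs (i, j) with abundance ``f_i * f_j`` are merged
    over unordered equivalence, so species (i, j) with i < j carries
    ``2 f_i f_j``.  Zero-abundance species are dropped; abundances sum
    to 1.
    """
    species: list[DuplexSpecies] = []
    k = len(mixture.alleles)
    for i in range(k):
        for j in range(i, k):
            ab = mixture.fractions[i] * mixture.fractions[j]
            if i != j:
                ab *= 2.0
            if ab == 0.0:
                continue
            a, b = mixture.alleles[i], mixture.alleles[j]
            offsets = tuple(
                pos + 1 for pos, (x, y) in enumerate(zip(a, b)) if x != y
            )
            species.append(DuplexSpecies(i, j, offsets, ab))
    return species


def heteroduplex_fraction(duplexes: list[DuplexSpecies]) -> float:
    """Total abundance of mismatch-carrying duplex species."""
    return sum(d.abundance for d in duplexes if d.is_heteroduplex)


def sn_fragments(amplicon: Region, mismatch_positions: list[int]) -> list[int]:
    """Double-stranded fragment sizes after complete mismatch cleavage.

    ``mismatch_positions`` are absolute template positions strictly inside
    the amplicon ``[s, e]``.  Each mismatch is excised by the staggered
    two-strand nicks, so k mismatches give k + 1 fragments whose sizes sum
    to ``region_length(amplicon) - k``; interior fragments between adjacent
    mismatches may have size 0.  Fragments are returned in template order.

    A single mismatch at p gives fragments ``p - s`` and ``e - p``
    (e.g. 139 and 190 bp for a 330-bp amplicon cut 139 bp in).
    """
    L = region_length(amplicon)
    offsets = sorted(_to_offset(amplicon, p) for p in mismatch_positions)
    if len(set(offsets)) != len(offsets):
        raise ValueError(f"duplicate mismatch positions: {mismatch_positions}")
    return fragments_from_offsets(L, offsets)


def fragments_from_offsets(amplicon_length: int, offsets: list[int]) -> list[int]:
    """Fragment sizes for 1-based mismatch offsets within an amplicon."""
    offs = sorted(offsets)
    for o in offs:
        if o <= 1 or o >= amplicon_length:
            raise ValueError(
                f"mismatch offset {o} at the boundary of a "
                f"{amplicon_length}-bp amplicon: cut is undefined"
            )
    if not offs:
        return [amplicon_length]
    sizes = [offs[0] - 1]
    sizes += [b - a - 1 for a, b in zip(offs, offs[1:])]
    sizes.append(amplicon_length - offs[-1])
    return sizes


def _to_offset(amplicon: Region, pos: int) -> int:
    """1-based offset of an absolute position inside a (possibly
    origin-spanning) amplicon."""
    s, e = amplicon.start, amplicon.end
    if s <= e:
        if not (s <= pos <= e):
            raise ValueError(f"position {pos} outside amplicon {s}-{e}")
        return pos - s + 1
    L = amplicon.genome_length
    assert L is not None
    if pos >= s:
        return pos - s + 1
    if pos <= e:
        return (L - s + 1) + pos
    raise ValueError(f"position {pos} outside wrapped amplicon {s}-{e}")


# ---------------------------------------------------------------------------
# Peak profiles
# ---------------------------------------------------------------------------

def _size_tolerance(size: float) -> float:
    """Sizing resolution of the readout: max(2 bp, 5 % of fragment size)."""
    return max(2.0, 0.05 * size)


def merge_peaks(peaks: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Combine peaks within sizing resolution of each other.

    Peaks are clustered greedily along the size axis; each cluster is
    replaced by its abundance-weighted mean size.  Total abundance is
    preserved.
    """
    if not peaks:
        return []
    peaks = sorted(peaks)
    clusters: list[list[tuple[float, float]]] = [[peaks[0]]]
    for size, ab in peaks[1:]:
        if size - clusters[-1][-1][0] <= _size_tolerance(size):
            clusters[-1].append((size, ab))
        else:
            clusters.append([(size, ab)])
    merged = []
    for cl in clusters:
        total = sum(ab for _, ab in cl)
        mean = sum(size * ab for size, ab in cl) / total if total > 0 else cl[0][0]
        merged.append((mean, total))
    return merged


@dataclass
class PeakProfile:
    """Detectable fragment sizes with mass-fraction abundances.

    ``raw_peaks`` keeps the full (merged, unfiltered) profile so that
    conservation can be checked; ``peaks`` is what the instrument would
    report after the detectability floor.
    """

    peaks: list[tuple[float, float]]
    label: str  # "uncut" | "cut"
    min_detectable_size: float = DEFAULT_MIN_DETECTABLE_SIZE
    raw_peaks: list[tuple[float, float]] = field(default_factory=list)

    @property
    def total_abundance(self) -> float:
        return sum(ab for _, ab in self.peaks)

    @property
    def raw_total_abundance(self) -> float:
        return sum(ab for _, ab in self.raw_peaks)

    def sizes(self) -> list[float]:
        return [s for s, _ in self.peaks]


def wave_hs_profile(
    duplexes: list[DuplexSpecies],
    amplicon: Region,
    min_detectable_size: float = DEFAULT_MIN_DETECTABLE_SIZE,
    cut: bool = False,
    digestion_efficiency: float = 1.0,
) -> PeakProfile:
    """Size-based peak profile of annealed (and optionally digested) DNA.

    Uncut: every duplex contributes one peak at the full amplicon length.
    Cut: mismatch-free duplexes stay at full length; each heteroduplex
    redistributes ``digestion_efficiency`` of its abundance onto its
    cleavage fragments, mass-weighted so total abundance stays 1.  Peaks
    within sizing resolution are merged, then peaks below
    ``min_detectable_size`` are removed (kept in ``raw_peaks``).
    """
    if not 0.0 <= digestion_efficiency <= 1.0:
        raise ValueError("digestion_efficiency must be in [0, 1]")
    L = region_length(amplicon)
    raw: list[tuple[float, float]] = []
    for d in duplexes:
        if not cut or not d.is_heteroduplex:
            raw.append((float(L), d.abundance))
            continue
        uncut_part = (1.0 - digestion_efficiency) * d.abundance
        if uncut_part > 0:
            raw.append((float(L), uncut_part))
        sizes = fragments_from_offsets(L, list(d.mismatch_offsets))
        total = sum(sizes)
        for s in sizes:
            if s > 0:
                raw.append((float(s), digestion_efficiency * d.abundance * s / total))
    merged = merge_peaks(raw)
    detectable = [(s, ab) for s, ab in merged if s >= min_detectable_size]
    return PeakProfile(
        peaks=detectable,
        label="cut" if cut else "uncut",
        min_detectable_size=min_detectable_size,
        raw_peaks=merged,
    )


def combine_profiles(
    profiles: list[tuple[PeakProfile, float]],
) -> PeakProfile:
    """Weighted superposition of peak profiles (same cut state).

    Used to pool products of different sizes amplified from the same
    reaction (e.g. the mtDNA-length product plus an off-size nuclear
    product); weights are template mass shares and should sum to 1.
    """
    if not profiles:
        raise ValueError("no profiles to combine")
    labels = {p.label for p, _ in profiles}
    if len(labels) != 1:
        raise ValueError(f"cannot combine profiles of mixed cut state: {labels}")
    floor = min(p.min_detectable_size for p, _ in profiles)
    raw = [
        (s, ab * w) for p, w in profiles for s, ab in p.raw_peaks
    ]
    merged = merge_peaks(raw)
    detectable = [(s, ab) for s, ab in merged if s >= floor]
    return PeakProfile(detectable, labels.pop(), floor, merged)


def dhplc_predict(
    duplexes: list[DuplexSpecies],
    min_fraction: float = DHPLC_MIN_HET_FRACTION,
) -> bool:
    """Whether a denaturing-HPLC run would show heteroduplex peaks.

    True iff total heteroduplex abundance reaches ``min_fraction``; the
    default is the abundance at a 5 % minor allele, the technique's
    empirical detection floor.
    """
    return heteroduplex_fraction(duplexes) >= min_fraction


@dataclass
class InterferenceCall:
    """Outcome of comparing total-DNA vs pure-mtDNA peak profiles."""

    interference: bool
    differing_peaks: list[tuple[float, float, float]]  # (size, ab_total, ab_mt)
    label: str


def call_interference(
    profile_total: PeakProfile,
    profile_mt: PeakProfile,
    tolerance: float = DEFAULT_ABUNDANCE_TOLERANCE,
) -> InterferenceCall:
    """Compare a total-DNA profile against a pure-mtDNA profile.

    Peaks from the two profiles are matched by size within sizing
    resolution.  A peak counts as present when its abundance exceeds
    ``tolerance``; a peak present in one profile but absent (unmatched, or
    matched below tolerance) in the other is a differing peak, and any
    differing peak makes the call "interference".  Shared peaks that merely
    differ in abundance are not differences: the readout is a peak-pattern
    comparison, not a quantitative one.  Profiles must come from the same
    cut state.
    """
    if profile_total.label != profile_mt.label:
        raise ValueError(
            f"profiles from different cut states: "
            f"{profile_total.label!r} vs {profile_mt.label!r}"
        )
    a = list(profile_total.peaks)
    b = list(profile_mt.peaks)
    matched_b: set[int] = set()
    differing: list[tuple[float, float, float]] = []
    for size_a, ab_a in a:
        best_j, best_d = None, None
        for j, (size_b, _) in enumerate(b):
            if j in matched_b:
                continue
            d = abs(size_a - size_b)
            if d <= _size_tolerance(max(size_a, size_b)) and (best_d is None or d < best_d):
                best_j, best_d = j, d
        if best_j is None:
            if ab_a > tolerance:
                differing.append((size_a, ab_a, 0.0))
        else:
            matched_b.add(best_j)
            ab_b = b[best_j][1]
            if (ab_a > tolerance) != (ab_b > tolerance):
                differing.append((size_a, ab_a, ab_b))
    for j, (size_b, ab_b) in enumerate(b):
        if j not in matched_b and ab_b > tolerance:
            differing.append((size_b, 0.0, ab_b))
    differing.sort()
    return InterferenceCall(
        interference=len(differing) > 0,
        differing_peaks=differing,
        label=profile_total.label,
    )
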