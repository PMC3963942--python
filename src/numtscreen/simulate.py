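"""Synthetic genomes, planted nuclear insertions, heteroplasmic mixtures.

Everything the screening and digestion stages consume can be generated
here, fully seeded, with the ground truth recorded at generation time:

* a circular mitochondrial-genome stand-in (random background, optionally
  with the catalogue's primer binding sites written in at their published
  coordinates, so every pair recovers its intended amplicon);
* linear "chromosome" records carrying copies of mtDNA regions mutated at a
  controlled substitution rate -- the synthetic counterpart of ancient
  mtDNA insertions that have drifted from the modern sequence;
* biallelic template mixtures over a dilution series of minor-allele
  fractions, the synthetic counterpart of a plasmid/blood heteroplasmy
  titration.

Divergence is substitution-only (the nuclear insertions of interest are
co-linear with the primers over amplicon scale) with a uniform choice among
the three alternative bases; this is a deliberate non-biological
simplification (no transition bias, no indels).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import (
    MT_GENOME_LENGTH,
    IUPAC_BITS,
    PrimerPair,
    SequenceRecord,
    revcomp,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Default minor-allele dilution series (0 = homoplasmic control).
DEFAULT_FRACTION_SERIES = (0.0, 0.02, 0.05, 0.10, 0.20, 0.50)

#: Gap left between successive copies of a multi-copy insertion, bp.
COPY_SPACING = 2000

#: Default synthetic chromosome length: large enough for flanking context
#: around multi-kb insertions, small enough for sub-second scans.
DEFAULT_CHROM_LENGTH = 200_000


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def make_mt_genome(
    length: int = MT_GENOME_LENGTH,
    gc: float = 0.44,
    seed: int = 0,
) -> SequenceRecord:
    """A circular random genome emulating mtDNA base composition.

    Defaults match the human mitochondrial genome: 16,569 bp, ~44 % GC.
    Fully reproducible under ``seed``.
    """
    if length < 1000:
        raise ValueError("mt genome length must be >= 1000")
    rng = np.random.default_rng([seed, 101])
    return SequenceRecord("mt_synthetic", _random_dna(rng, length, gc), "circular")


def embed_primer_sites(
    genome: SequenceRecord,
    pairs: list[PrimerPair],
) -> tuple[SequenceRecord, list[int]]:
    """Write each pair's primer binding sites into a circular genome.

    The forward primer sequence is placed at the first bases of the pair's
    target region and the reverse complement of the reverse primer at the
    last bases, so that every pair amplifies its published target exactly.
    Overlapping footprints from different pairs are allowed when they
    demand the same base; conflicting demands keep the first-written base
    and are reported (position list) and warned about.  Degenerate primer
    codes are resolved to the lexicographically smallest compatible base.
    """
    if not genome.circular:
        raise ValueError("primer-site embedding expects a circular genome")
    n = len(genome.sequence)
    seq = bytearray(genome.sequence, "ascii")
    claimed: dict[int, str] = {}
    conflicts: list[int] = []

    def place(site: str, start0: int) -> None:
        for k, code in enumerate(site):
            base = code if code in "ACGT" else min(
                b for b in "ACGT" if IUPAC_BITS[b] & IUPAC_BITS[code]
            )
            pos = (start0 + k) % n
            prev = claimed.get(pos)
            if prev is None:
                claimed[pos] = base
                seq[pos] = ord(base)
            elif prev != base:
                conflicts.append(pos + 1)

    for pair in pairs:
        place(pair.forward.sequence, pair.target.start - 1)
        rc = revcomp(pair.reverse.sequence)
        place(rc, (pair.target.end - len(rc)) % n)
    if conflicts:
        logger.warning(
            "primer-site embedding: %d conflicting position(s), first-written "
            "base kept: %s", len(conflicts), sorted(set(conflicts))[:10],
        )
    return SequenceRecord(genome.id, seq.decode("ascii"), "circular"), sorted(set(conflicts))


@dataclass
class NumtSpec:
    """One planted nuclear copy (or tandem family) of an mtDNA region.

    ``divergence`` is the per-site substitution probability over the whole
    copy; ``footprint_divergence``, when set, overrides it inside the two
    primer footprints (first/last bases of the copy), which lets dense
    interior divergence coexist with amplifiable primer sites -- the
    configuration under which nuclear products cleave into many fragments.
    Footprint lengths are taken from ``pair`` when given.
    """

    source_start: int
    source_end: int
    divergence: float
    chrom_id: str = "chr1"
    position: int = 10_000
    copy_number: int = 1
    pair: PrimerPair | None = None
    footprint_divergence: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 0.2:
            raise ValueError(f"divergence {self.divergence} outside [0, 0.2]")
        if self.footprint_divergence is not None and not (
            0.0 <= self.footprint_divergence <= 0.2
        ):
            raise ValueError("footprint_divergence outside [0, 0.2]")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")

    @property
    def pair_id(self) -> str:
        return self.pair.id if self.pair is not None else ""


def _mutate(
    rng: np.random.Generator,
    seq: str,
    rates: np.ndarray,
) -> tuple[str, np.ndarray]:
    """Substitute each base independently with its per-site probability.

    Returns the mutated sequence and the 0-based substituted positions.
    Substitutions are uniform over the three alternative bases.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rates
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii"), idx


def plant_numts(
    mt: SequenceRecord,
    specs: list[NumtSpec],
    chrom_length: int = DEFAULT_CHROM_LENGTH,
    seed: int = 0,
    gc: float = 0.41,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate chromosomes carrying mutated copies of mtDNA regions.

    Each spec's source region is substituted i.i.d. at the spec's rate(s)
    once, and that single realization is written over the random chromosome
    background at the recorded position(s): multi-copy specs model a family
    expanded by segmental duplication after one integration event, so all
    copies are identical.  Coordinates stay fixed (overwrite, no length
    change); further copies go downstream at a fixed spacing.  Overlapping
    insertions on one chromosome are an error.

    Returns the chromosome records plus a ground-truth table with one row
    per planted copy: coordinates, realized substitution count, divergence,
    the 1-based substitution offsets within the copy, and the substitution
    counts inside the two primer footprints when the spec names a pair.
    """
    chrom_ids = sorted({s.chrom_id for s in specs})
    backgrounds = {
        cid: bytearray(
            _random_dna(np.random.default_rng([seed, 1, k]), chrom_length, gc),
            "ascii",
        )
        for k, cid in enumerate(chrom_ids)
    }
    occupied: dict[str, list[tuple[int, int]]] = {cid: [] for cid in chrom_ids}
    rows = []
    rng = np.random.default_rng([seed, 2])
    for spec in specs:
        source = mt.fetch(spec.source_start, spec.source_end)
        m = len(source)
        rates = np.full(m, spec.divergence)
        fp_len_5 = fp_len_3 = 0
        if spec.pair is not None:
            fp_len_5 = len(spec.pair.forward)
            fp_len_3 = len(spec.pair.reverse)
            if spec.footprint_divergence is not None:
                rates[:fp_len_5] = spec.footprint_divergence
                rates[m - fp_len_3 :] = spec.footprint_divergence
        mutated, subs = _mutate(rng, source, rates)
        for copy_i in range(spec.copy_number):
            start0 = spec.position - 1 + copy_i * (m + COPY_SPACING)
            end0 = start0 + m  # exclusive
            if start0 < 0 or end0 > chrom_length:
                raise ValueError(
                    f"insertion {spec.chrom_id}:{start0 + 1}-{end0} outside "
                    f"chromosome of length {chrom_length}"
                )
            for a, b in occupied[spec.chrom_id]:
                if start0 < b and a < end0:
                    raise ValueError(
                        f"overlapping insertions on {spec.chrom_id} at "
                        f"{start0 + 1}-{end0} vs {a + 1}-{b}"
                    )
            occupied[spec.chrom_id].append((start0, end0))
            backgrounds[spec.chrom_id][start0:end0] = mutated.encode("ascii")
            rows.append({
                "chrom": spec.chrom_id,
                "insert_start": start0 + 1,
                "insert_end": end0,
                "pair_id": spec.pair_id,
                "source_start": spec.source_start,
                "source_end": spec.source_end,
                "n_substitutions": int(subs.size),
                "realized_divergence": subs.size / m,
                "substitution_offsets": ",".join(str(int(i) + 1) for i in subs),
                "fwd_footprint_mismatches": (
                    int((subs < fp_len_5).sum()) if spec.pair else pd.NA
                ),
                "rev_footprint_mismatches": (
                    int((subs >= m - fp_len_3).sum()) if spec.pair else pd.NA
                ),
            })
    chroms = [
        SequenceRecord(cid, backgrounds[cid].decode("ascii"), "linear")
        for cid in chrom_ids
    ]
    truth = pd.DataFrame(
        rows,
        columns=[
            "chrom", "insert_start", "insert_end", "pair_id",
            "source_start", "source_end", "n_substitutions",
            "realized_divergence", "substitution_offsets",
            "fwd_footprint_mismatches", "rev_footprint_mismatches",
        ],
    )
    return chroms, truth


@dataclass
class MixtureSpec:
    """A biallelic dilution series over one amplicon.

    The minor allele differs from ``major_seq`` at exactly one position
    (``snp_offset``, 1-based, strictly interior so the cleavage site is
    defined).  Fractions are minor-allele template shares in [0, 0.5].
    """

    major_seq: str
    snp_offset: int
    snp_base: str
    fractions: tuple[float, ...] = DEFAULT_FRACTION_SERIES
    seed: int | None = None  # provenance only; generation is deterministic

    def __post_init__(self) -> None:
        L = len(self.major_seq)
        if not 1 < self.snp_offset < L:
            raise ValueError(
                f"SNP offset {self.snp_offset} not strictly inside the "
                f"{L}-bp amplicon"
            )
        if self.snp_base not in "ACGT":
            raise ValueError(f"snp_base must be A/C/G/T: {self.snp_base!r}")
        if self.major_seq[self.snp_offset - 1].upper() == self.snp_base:
            raise ValueError("minor allele identical to major at the SNP")
        if any(not 0.0 <= f <= 0.5 for f in self.fractions):
            raise ValueError("minor fractions must lie in [0, 0.5]")

    @property
    def minor_seq(self) -> str:
        s = self.major_seq.upper()
        i = self.snp_offset - 1
        return s[:i] + self.snp_base + s[i + 1 :]


def make_mixture(spec: MixtureSpec):
    """One TemplateMixture per fraction in the spec's dilution series."""
    from .duplex import TemplateMixture

    major, minor = spec.major_seq.upper(), spec.minor_seq
    return [
        TemplateMixture(
            alleles=[major, minor],
            fractions=[1.0 - f, f],
            names=["major", "minor"],
        )
        for f in spec.fractions
    ]
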