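"""Primer catalogues, sequence I/O and circular-coordinate arithmetic.

The human mitochondrial genome is a 16,569-bp circle; published primer
catalogues give their amplicon targets as 1-based inclusive ``start-end``
intervals on the rCRS coordinate system, with origin-spanning amplicons
written as ``start > end`` (e.g. ``16344-276``).  Everything downstream
(site scanning, amplicon prediction, fragment modelling) works in those
coordinates, so the conversions live here and nowhere else.

Two catalogues ship with the package as TSV fixtures: the 48-pair "DM" set
(DHPLC-oriented, ~200-600 bp amplicons) and the 17-pair "SB" set
(nuclease-assay-oriented, ~2-kb amplicons).  A third fixture transcribes the
published per-pair NUMT match annotations, including rows whose printed
positions or match symbols are not interpretable; those rows carry an
explicit ``status`` flag rather than being silently repaired.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Length of the human mitochondrial genome (rCRS), in bp.
MT_GENOME_LENGTH = 16569

#: Upper-case IUPAC nucleotide codes accepted in primers and templates.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

#: Bit-set expansion of each IUPAC code (A=1, C=2, G=4, T=8).  Two coded
#: bases are compatible iff their bit sets intersect.
IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 1 | 2 | 4 | 8,
}

#: Primers shorter than this trigger a specificity warning (configurable
#: per call); typical mtDNA walking primers are 17-31 nt.
MIN_PRIMER_LENGTH_WARN = 15


class CoordinateError(ValueError):
    """Raised for invalid genomic regions or coordinates."""


class SequenceParseError(ValueError):
    """Raised for malformed sequence or table input."""


def _validate_seq(seq: str, what: str = "sequence") -> str:
    s = seq.strip().upper()
    if not s:
        raise SequenceParseError(f"empty {what}")
    bad = set(s) - IUPAC_ALPHABET
    if bad:
        raise SequenceParseError(
            f"non-IUPAC character(s) {sorted(bad)} in {what}: {seq!r}"
        )
    return s


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, S<->S, ...); an involution."""
    s = _validate_seq(seq)
    return str(Seq(s).reverse_complement())


@dataclass(frozen=True)
class Region:
    """1-based inclusive interval, optionally on a circular genome.

    On a circular genome a region with ``start > end`` wraps through the
    origin (between position ``genome_length`` and position 1).
    """

    start: int
    end: int
    circular: bool = False
    genome_length: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise CoordinateError(f"coordinates must be >= 1: {self}")
        if self.circular:
            if self.genome_length is None:
                raise CoordinateError(
                    "circular region requires genome_length"
                )
            if self.start > self.genome_length or self.end > self.genome_length:
                raise CoordinateError(
                    f"coordinate beyond genome_length={self.genome_length}: {self}"
                )
        elif self.start > self.end:
            raise CoordinateError(
                f"start > end on a linear region: {self} "
                "(wrap-around requires circular=True)"
            )

    def __len__(self) -> int:
        return region_length(self)

    def wraps_origin(self) -> bool:
        return self.circular and self.start > self.end


def region_length(r: Region) -> int:
    """Length in bp of a 1-based inclusive region.

    Origin-spanning circular regions (start > end) cover
    ``(L - start + 1) + end`` bases, e.g. 16344-276 on the 16,569-bp
    mitochondrial circle covers 502 bp.
    """
    if r.start <= r.end:
        return r.end - r.start + 1
    assert r.circular and r.genome_length is not None
    return (r.genome_length - r.start + 1) + r.end


@dataclass(frozen=True)
class Primer:
    """A PCR primer, written 5'->3'."""

    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_seq(self.sequence, f"primer {self.name}"))
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward|reverse: {self.orientation}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair and its intended mtDNA target region.

    ``expected_size`` is always the arithmetic length of ``target``; when a
    published catalogue prints a different size the printed value is kept in
    ``printed_size`` and a warning is emitted, never silently adopted.
    """

    id: str
    forward: Primer
    reverse: Primer
    target: Region
    printed_size: int | None = None
    expected_size: int = field(init=False)

    def __post_init__(self) -> None:
        if self.forward.orientation != "forward" or self.reverse.orientation != "reverse":
            raise ValueError(f"pair {self.id}: primer orientations are inconsistent")
        object.__setattr__(self, "expected_size", region_length(self.target))

    @property
    def size_consistent(self) -> bool:
        """Whether the printed amplicon size agrees with the coordinates."""
        return self.printed_size is None or self.printed_size == self.expected_size


@dataclass
class SequenceRecord:
    """A named DNA sequence with linear or circular topology."""

    id: str
    sequence: str
    topology: str = "linear"  # "linear" | "circular"

    def __post_init__(self) -> None:
        self.sequence = _validate_seq(self.sequence, f"record {self.id}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear|circular: {self.topology}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive region ``start..end``.

        On circular records ``start > end`` wraps through the origin.
        """
        n = len(self.sequence)
        if not (1 <= start <= n and 1 <= end <= n):
            raise CoordinateError(f"{start}..{end} outside record of length {n}")
        if start <= end:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise CoordinateError(f"wrap-around fetch {start}..{end} on linear record")
        return self.sequence[start - 1 :] + self.sequence[:end]

    def region(self, start: int, end: int) -> Region:
        return Region(start, end, circular=self.circular,
                      genome_length=len(self.sequence) if self.circular else None)


# ---------------------------------------------------------------------------
# Primer tables
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("id", "forward_seq", "reverse_seq", "target_start", "target_end")


def load_primer_table(
    path: str | Path,
    *,
    mt_length: int = MT_GENOME_LENGTH,
    min_primer_length: int = MIN_PRIMER_LENGTH_WARN,
) -> list[PrimerPair]:
    """Load a TSV primer-pair table.

    Required columns: id, forward_seq, reverse_seq, target_start,
    target_end.  An optional printed_size_bp column carries the amplicon
    size as published; disagreements with the coordinate arithmetic are
    warned about and preserved on the pair.  Targets are interpreted on the
    circular mitochondrial coordinate system of length ``mt_length``, so
    ``start > end`` denotes an origin-spanning amplicon.
    """
    path = Path(path)
    pairs: list[PrimerPair] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            logger.warning("%s: empty primer table", path)
            return []
        missing = set(_REQUIRED_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SequenceParseError(f"{path}: missing column(s) {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                pid = row["id"].strip()
                if not pid:
                    raise SequenceParseError("empty id")
                if pid in seen:
                    raise SequenceParseError(f"duplicate id {pid!r}")
                fwd = Primer(f"{pid}_F", row["forward_seq"], "forward")
                rev = Primer(f"{pid}_R", row["reverse_seq"], "reverse")
                target = Region(
                    int(row["target_start"]), int(row["target_end"]),
                    circular=True, genome_length=mt_length,
                )
                printed = row.get("printed_size_bp")
                printed_size = int(printed) if printed not in (None, "") else None
                pair = PrimerPair(pid, fwd, rev, target, printed_size=printed_size)
            except (ValueError, KeyError) as exc:
                raise SequenceParseError(f"{path}:{lineno}: {exc}") from exc
            for primer in (fwd, rev):
                if len(primer) < min_primer_length:
                    logger.warning(
                        "%s:%d: primer %s is only %d nt (< %d)",
                        path, lineno, primer.name, len(primer), min_primer_length,
                    )
            if not pair.size_consistent:
                logger.warning(
                    "%s:%d: pair %s printed size %d bp disagrees with "
                    "coordinate arithmetic (%d bp); keeping both",
                    path, lineno, pid, pair.printed_size, pair.expected_size,
                )
            seen.add(pid)
            pairs.append(pair)
    if not pairs:
        logger.warning("%s: primer table has no data rows", path)
    return pairs


def _data_path(name: str):
    return resources.files("numtscreen.data").joinpath(name)


def load_dm_primers() -> list[PrimerPair]:
    """The bundled 48-pair DM catalogue (short, DHPLC-scale amplicons)."""
    with resources.as_file(_data_path("dm_primers.tsv")) as p:
        return load_primer_table(p)


def load_sb_primers() -> list[PrimerPair]:
    """The bundled 17-pair SB catalogue (~2-kb amplicons)."""
    with resources.as_file(_data_path("sb_primers.tsv")) as p:
        return load_primer_table(p)


def load_all_primers() -> list[PrimerPair]:
    """All 65 bundled primer pairs (DM then SB)."""
    return load_dm_primers() + load_sb_primers()


def load_numt_matches() -> pd.DataFrame:
    """Published per-pair NUMT match annotations, as transcribed.

    Returns a DataFrame with one row per (pair, accession) match.  The
    ``status`` column flags rows that cannot be taken at face value:
    ``unparseable_position`` (position printed without a separator),
    ``inconsistent_position`` (end before start), ``undefined_symbol``
    (a match symbol the source never defines) and ``incomplete``.
    ``start``/``end`` are parsed from ``position_printed`` where possible.
    """
    with resources.as_file(_data_path("numt_matches.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str).fillna("")
    starts, ends = [], []
    for pos, status in zip(df["position_printed"], df["status"]):
        a = b = None
        if status in ("ok", "undefined_symbol") and "–" in pos:
            left, _, right = pos.partition("–")
            try:
                a, b = int(left), int(right)
            except ValueError:
                a = b = None
        starts.append(a)
        ends.append(b)
    df["start"] = pd.array(starts, dtype="Int64")
    df["end"] = pd.array(ends, dtype="Int64")
    df["size_printed_bp"] = pd.to_numeric(df["size_printed_bp"], errors="coerce").astype("Int64")
    return df


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

_TOPOLOGY_TOKEN = "[topology=circular]"


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records; a ``[topology=circular]`` description token marks
    circular records.  Sequences are normalised to upper case."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceParseError(f"{path}: duplicate record id {rec.id!r}")
        if len(rec.seq) == 0:
            raise SequenceParseError(f"{path}: empty sequence for {rec.id!r}")
        topology = "circular" if _TOPOLOGY_TOKEN in rec.description else "linear"
        records.append(SequenceRecord(rec.id, str(rec.seq), topology))
        seen.add(rec.id)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, carrying topology in the description."""
    out = []
    for r in records:
        desc = _TOPOLOGY_TOKEN if r.circular else ""
        out.append(SeqRecord(Seq(r.sequence), id=r.id, description=desc))
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# Primer footprints on the target genome
# ---------------------------------------------------------------------------

def _wrap(pos: int, L: int) -> int:
    """Map an integer onto 1..L circularly."""
    return (pos - 1) % L + 1


def target_footprints(pair: PrimerPair) -> tuple[Region, Region]:
    """Regions covered by the two primers inside the pair's target.

    The forward primer occupies the first ``len(forward)`` bases of the
    target; the reverse primer binds the minus strand over the last
    ``len(reverse)`` bases.  Both are returned in plus-strand coordinates
    and may wrap the origin on the circular genome.
    """
    t = pair.target
    L = t.genome_length
    if L is None:
        raise CoordinateError(f"pair {pair.id}: target has no genome_length")
    f_start = t.start
    f_end = _wrap(t.start + len(pair.forward) - 1, L)
    r_end = t.end
    r_start = _wrap(t.end - len(pair.reverse) + 1, L)
    return (
        Region(f_start, f_end, circular=True, genome_length=L),
        Region(r_start, r_end, circular=True, genome_length=L),
    )
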