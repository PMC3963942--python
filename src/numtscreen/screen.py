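"""Pair convergent primer hits into predicted amplicons; NUMT screen.

The co-amplification screen asks, for every primer pair, whether both
primers bind the same nuclear template in convergent orientation close
enough together to yield a PCR product.  Product extent follows the
5'-to-5' convention: the amplicon runs from the forward primer's 5' end to
the reverse primer's 5' end inclusive, which makes a perfectly matching
nuclear insertion produce a product exactly as long as the mitochondrial
target amplicon.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .catalog import PrimerPair, Region, SequenceRecord, region_length
from .search import (
    DEFAULT_MAX_MISMATCHES,
    PairMatchClass,
    PrimerHit,
    classify_match,
    classify_pair,
    scan_primer,
)

logger = logging.getLogger(__name__)

#: Extra slack beyond twice the expected product size when bounding how far
#: apart convergent hits may sit and still count as an amplicon.
PRODUCT_LENGTH_SLACK = 1000


def default_max_product_length(pair: PrimerPair) -> int:
    return 2 * pair.expected_size + PRODUCT_LENGTH_SLACK


@dataclass(frozen=True)
class PredictedAmplicon:
    """A convergent forward/reverse hit pair on one template."""

    template_id: str
    region: Region
    length: int
    forward_hit: PrimerHit
    reverse_hit: PrimerHit
    pair_class: PairMatchClass
    is_target: bool = False

    @property
    def total_mismatches(self) -> int:
        return self.forward_hit.mismatches + self.reverse_hit.mismatches


def predict_amplicons(
    pair: PrimerPair,
    template: SequenceRecord,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    max_product_length: int | None = None,
    *,
    require_three_prime_match: bool = False,
    is_mt_reference: bool = False,
) -> list[PredictedAmplicon]:
    """All PCR products the pair could form on one template.

    Every combination of a forward-primer hit and a reverse-primer hit on
    opposite strands, in convergent orientation with the product no longer
    than ``max_product_length`` (default ``2 * expected_size + 1000``),
    becomes one PredictedAmplicon.  Circular templates allow
    origin-spanning products.  Divergent or too-distant hit pairs yield
    nothing.  With ``require_three_prime_match`` both hits must pair their
    3'-terminal base (extension feasibility).
    """
    if max_product_length is None:
        max_product_length = default_max_product_length(pair)
    n = len(template.sequence)
    fwd_hits = scan_primer(pair.forward, template, max_mismatches)
    rev_hits = scan_primer(pair.reverse, template, max_mismatches)
    if require_three_prime_match:
        fwd_hits = [h for h in fwd_hits if h.three_prime_terminal_match]
        rev_hits = [h for h in rev_hits if h.three_prime_terminal_match]

    min_len = max(len(pair.forward), len(pair.reverse))
    out: list[PredictedAmplicon] = []
    for fh in fwd_hits:
        for rh in rev_hits:
            if fh.strand == rh.strand:
                continue
            # product runs 5'->3' from the plus-strand primer's start to the
            # minus-strand primer's start
            if fh.strand == "plus":
                start, end = fh.start, rh.start
            else:
                start, end = rh.start, fh.start
            if start <= end:
                length = end - start + 1
            elif template.circular:
                length = (n - start + 1) + end
            else:
                continue  # divergent on a linear template
            if length < min_len or length > max_product_length:
                continue
            region = Region(
                start, end,
                circular=template.circular,
                genome_length=n if template.circular else None,
            )
            pair_class = classify_pair(classify_match(fh), classify_match(rh))
            is_target = bool(
                is_mt_reference
                and start == pair.target.start
                and end == pair.target.end
            )
            out.append(
                PredictedAmplicon(
                    template_id=template.id,
                    region=region,
                    length=length,
                    forward_hit=fh,
                    reverse_hit=rh,
                    pair_class=pair_class,
                    is_target=is_target,
                )
            )
    out.sort(key=lambda a: (a.region.start, a.region.end, a.pair_class.symbol))
    return out


@dataclass
class PairScreenResult:
    """Screen outcome for one primer pair."""

    pair_id: str
    nuclear_amplicons: list[PredictedAmplicon] = field(default_factory=list)
    target_amplicon: PredictedAmplicon | None = None
    target_recovered: bool = False

    @property
    def risk_flag(self) -> bool:
        """True iff at least one nuclear amplicon was predicted."""
        return len(self.nuclear_amplicons) > 0


@dataclass
class ScreenReport:
    """Per-pair NUMT co-amplification screening results."""

    results: dict[str, PairScreenResult]

    def flagged_pairs(self) -> list[str]:
        return sorted(pid for pid, r in self.results.items() if r.risk_flag)

    def unrecovered_pairs(self) -> list[str]:
        return sorted(
            pid for pid, r in self.results.items() if not r.target_recovered
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per (pair, nuclear amplicon), mirroring the published
        screening-table columns; pairs without nuclear amplicons get a
        single row with empty location fields."""
        rows = []
        for pid in sorted(self.results):
            r = self.results[pid]
            base = {
                "pair_id": pid,
                "risk_flag": r.risk_flag,
                "target_recovered": r.target_recovered,
            }
            if not r.nuclear_amplicons:
                rows.append({**base, "template_id": "", "pair_class": "",
                             "start": pd.NA, "end": pd.NA, "size_bp": pd.NA})
            for a in r.nuclear_amplicons:
                rows.append({
                    **base,
                    "template_id": a.template_id,
                    "pair_class": a.pair_class.symbol,
                    "start": a.region.start,
                    "end": a.region.end,
                    "size_bp": a.length,
                })
        df = pd.DataFrame(rows)
        return df.sort_values(
            ["pair_id", "template_id", "start"], na_position="last"
        ).reset_index(drop=True)


def screen_primer_set(
    pairs: list[PrimerPair],
    db: list[SequenceRecord],
    mt_ref: SequenceRecord | None = None,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    max_product_length: int | None = None,
    *,
    require_three_prime_match: bool = False,
) -> ScreenReport:
    """Screen every pair against nuclear templates (and the mtDNA target).

    ``db`` holds the nuclear/NUMT-bearing templates; any amplicon there is a
    putative NUMT product and raises the pair's risk flag.  When ``mt_ref``
    is given each pair is additionally checked to recover its intended
    target amplicon; failure is flagged (``target_recovered=False``), not
    fatal.  Results are independent of the ordering of ``db``.
    """
    if not pairs:
        raise ValueError("empty primer-pair list")
    results: dict[str, PairScreenResult] = {}
    for pair in pairs:
        res = PairScreenResult(pair_id=pair.id)
        for template in sorted(db, key=lambda t: t.id):
            res.nuclear_amplicons.extend(
                predict_amplicons(
                    pair, template, max_mismatches, max_product_length,
                    require_three_prime_match=require_three_prime_match,
                )
            )
        res.nuclear_amplicons.sort(
            key=lambda a: (a.template_id, a.region.start, a.region.end)
        )
        if mt_ref is not None:
            mt_amps = predict_amplicons(
                pair, mt_ref, max_mismatches, max_product_length,
                require_three_prime_match=require_three_prime_match,
                is_mt_reference=True,
            )
            targets = [a for a in mt_amps if a.is_target]
            if targets:
                res.target_amplicon = targets[0]
                res.target_recovered = True
            else:
                logger.warning(
                    "pair %s: intended mtDNA target %d-%d not recovered",
                    pair.id, pair.target.start, pair.target.end,
                )
        results[pair.id] = res
    return ScreenReport(results=results)
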