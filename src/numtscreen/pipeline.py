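"""End-to-end screening pipeline: simulate -> screen -> digest -> compare.

A single run emulates the full evaluation strategy for a primer catalogue:

1. build a circular mtDNA stand-in carrying every pair's binding sites at
   the published coordinates;
2. plant nuclear copies of chosen target regions at controlled divergence
   ("NUMT" insertions) on synthetic chromosomes;
3. screen all pairs for nuclear co-amplification (bioinformatic risk);
4. for every pair, model the annealed duplexes and nuclease-cleavage peak
   profiles of a total-DNA template (mtDNA + nuclear products, weighted by
   copy number) and of a pure-mtDNA template, uncut and cut;
5. call interference wherever the two chromatogram profiles differ in
   detectable peaks.

The run is deterministic under (config, seed); every report carries the
tool version, the config hash and the seed.
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import (
    MT_GENOME_LENGTH,
    PrimerPair,
    SequenceRecord,
    load_all_primers,
    load_dm_primers,
    load_primer_table,
    load_sb_primers,
    write_fasta,
)
from .duplex import (
    DEFAULT_ABUNDANCE_TOLERANCE,
    DEFAULT_MIN_DETECTABLE_SIZE,
    InterferenceCall,
    PeakProfile,
    TemplateMixture,
    anneal,
    call_interference,
    combine_profiles,
    dhplc_predict,
    heteroduplex_fraction,
    wave_hs_profile,
)
from .screen import ScreenReport, screen_primer_set
from .search import DEFAULT_MAX_MISMATCHES
from .simulate import (
    DEFAULT_CHROM_LENGTH,
    NumtSpec,
    embed_primer_sites,
    make_mt_genome,
    plant_numts,
)


@dataclass
class NumtConfig:
    """One planted NUMT family in a pipeline run (targets a primer pair)."""

    pair_id: str
    divergence: float
    chrom_id: str = "chr1"
    position: int = 10_000
    copy_number: int = 1
    footprint_divergence: float | None = None


@dataclass
class RunConfig:
    """All parameters of a pipeline run; YAML round-trippable."""

    seed: int = 0
    primers: str = "all"  # "all" | "dm" | "sb" | path to a TSV table
    max_mismatches: int = DEFAULT_MAX_MISMATCHES
    max_product_length: int | None = None  # None: 2*expected + 1000 per pair
    min_detectable_size: float = DEFAULT_MIN_DETECTABLE_SIZE
    digestion_efficiency: float = 1.0
    abundance_tolerance: float = DEFAULT_ABUNDANCE_TOLERANCE
    mt_length: int = MT_GENOME_LENGTH
    gc: float = 0.44
    chrom_length: int = DEFAULT_CHROM_LENGTH
    mt_copies: int = 200  # mtDNA templates per nuclear NUMT copy
    numts: list[NumtConfig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.max_mismatches < 0 or self.mt_copies < 1:
            raise ValueError("max_mismatches >= 0 and mt_copies >= 1 required")
        if not 0.0 <= self.digestion_efficiency <= 1.0:
            raise ValueError("digestion_efficiency outside [0, 1]")
        self.numts = [
            n if isinstance(n, NumtConfig) else NumtConfig(**n) for n in self.numts
        ]

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    def config_hash(self) -> str:
        """Stable digest of all parameters (changes iff any one changes)."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def demo_config(seed: int = 0) -> RunConfig:
    """A self-contained demonstration run.

    Four target regions of the bundled 65-pair catalogue get planted
    nuclear copies spanning the qualitative regimes: an identical-sequence
    family (amplifiable, but indistinguishable products), two lightly
    diverged families (a few interior mismatches, cleavage fragments large
    enough to detect) and one heavily diverged family whose fragments fall
    below the 100-bp detectability floor.  Primer footprints are kept
    undiverged so all four families are amplifiable (risk-flagged).
    """
    return RunConfig(
        seed=seed,
        primers="all",
        numts=[
            NumtConfig("DM#5", 0.0, "chr11", 20_000, copy_number=5),
            NumtConfig("DM#18", 0.15, "chr6", 30_000, copy_number=10,
                       footprint_divergence=0.0),
            NumtConfig("DM#22", 0.004, "chr1", 40_000, copy_number=10,
                       footprint_divergence=0.0),
            NumtConfig("DM#38", 0.006, "chr5", 50_000, copy_number=10,
                       footprint_divergence=0.0),
        ],
    )


def provenance(config: RunConfig) -> dict:
    """Metadata block recorded in every report."""
    return {
        "tool": "numtscreen",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def _load_pairs(config: RunConfig) -> list[PrimerPair]:
    if config.primers == "all":
        return load_all_primers()
    if config.primers == "dm":
        return load_dm_primers()
    if config.primers == "sb":
        return load_sb_primers()
    return load_primer_table(config.primers, mt_length=config.mt_length)


@dataclass
class PairVerdict:
    """Combined bioinformatic + interference verdict for one pair."""

    pair_id: str
    risk_flag: bool
    target_recovered: bool
    n_nuclear_amplicons: int
    numt_fraction: float
    het_fraction_total: float
    dhplc_total: bool
    dhplc_mt: bool
    call_uncut: InterferenceCall
    call_cut: InterferenceCall

    @property
    def interference(self) -> bool:
        return self.call_uncut.interference or self.call_cut.interference


@dataclass
class PipelineResult:
    config: RunConfig
    pairs: list[PrimerPair]
    mt_genome: SequenceRecord
    chromosomes: list[SequenceRecord]
    truth: pd.DataFrame
    screen: ScreenReport
    verdicts: dict[str, PairVerdict]
    profiles: dict[str, dict[str, PeakProfile]]

    def verdict_frame(self) -> pd.DataFrame:
        rows = []
        for pid in sorted(self.verdicts):
            v = self.verdicts[pid]
            rows.append({
                "pair_id": pid,
                "risk_flag": v.risk_flag,
                "target_recovered": v.target_recovered,
                "n_nuclear_amplicons": v.n_nuclear_amplicons,
                "numt_fraction": round(v.numt_fraction, 6),
                "het_fraction_total": round(v.het_fraction_total, 6),
                "dhplc_total": v.dhplc_total,
                "dhplc_mt": v.dhplc_mt,
                "interference_uncut": v.call_uncut.interference,
                "interference_cut": v.call_cut.interference,
                "interference": v.interference,
                "differing_peaks": ";".join(
                    f"{s:.1f}bp({a:.4f}|{b:.4f})"
                    for s, a, b in v.call_uncut.differing_peaks
                    + v.call_cut.differing_peaks
                ),
            })
        return pd.DataFrame(rows)


def _pair_profiles(
    pair: PrimerPair,
    mt_allele: str,
    nuclear_alleles: list[str],
    config: RunConfig,
) -> tuple[dict[str, PeakProfile], float, float, bool, bool]:
    """Uncut/cut profiles for total-DNA and mtDNA-only templates.

    Template weights: ``mt_copies`` for the mtDNA allele, one per nuclear
    amplicon copy.  Nuclear products of the same length as the mtDNA
    amplicon co-anneal with it; off-size products cannot form gapless
    heteroduplexes with it and are modelled as independent full-length
    peaks superimposed by template share.
    """
    L = len(mt_allele)
    same = [s for s in nuclear_alleles if len(s) == L]
    off = [s for s in nuclear_alleles if len(s) != L]
    total_templates = config.mt_copies + len(nuclear_alleles)
    numt_fraction = len(nuclear_alleles) / total_templates

    # collapse identical alleles so fractions stay well-conditioned
    def mixture(weighted: dict[str, float]) -> TemplateMixture:
        total = sum(weighted.values())
        alleles = sorted(weighted)
        return TemplateMixture(
            alleles=alleles,
            fractions=[weighted[a] / total for a in alleles],
        )

    weighted: dict[str, float] = {mt_allele: float(config.mt_copies)}
    for s in same:
        weighted[s] = weighted.get(s, 0.0) + 1.0
    mix_total = mixture(weighted)
    mix_mt = TemplateMixture(alleles=[mt_allele], fractions=[1.0])

    dup_total = anneal(mix_total)
    dup_mt = anneal(mix_mt)

    from .catalog import Region

    region_mt = Region(1, L)
    in_mix_share = (config.mt_copies + len(same)) / total_templates
    profiles: dict[str, PeakProfile] = {}
    for cut in (False, True):
        label = "cut" if cut else "uncut"
        p_mix = wave_hs_profile(
            dup_total, region_mt, config.min_detectable_size, cut,
            config.digestion_efficiency,
        )
        parts = [(p_mix, in_mix_share)]
        for s in off:
            p_off = wave_hs_profile(
                anneal(TemplateMixture([s], [1.0])), Region(1, len(s)),
                config.min_detectable_size, cut, config.digestion_efficiency,
            )
            parts.append((p_off, 1.0 / total_templates))
        profiles[f"total_{label}"] = (
            combine_profiles(parts) if len(parts) > 1 else p_mix
        )
        profiles[f"mt_{label}"] = wave_hs_profile(
            dup_mt, region_mt, config.min_detectable_size, cut,
            config.digestion_efficiency,
        )
    return (
        profiles,
        numt_fraction,
        heteroduplex_fraction(dup_total),
        dhplc_predict(dup_total),
        dhplc_predict(dup_mt),
    )


def run_full_screen(config: RunConfig) -> PipelineResult:
    """Execute simulate -> screen -> digest -> compare for one config."""
    pairs = _load_pairs(config)
    by_id = {p.id: p for p in pairs}
    genome = make_mt_genome(config.mt_length, config.gc, config.seed)
    genome, _ = embed_primer_sites(genome, pairs)

    specs = []
    for nc in config.numts:
        if nc.pair_id not in by_id:
            raise ValueError(f"numts entry names unknown pair {nc.pair_id!r}")
        pair = by_id[nc.pair_id]
        specs.append(NumtSpec(
            source_start=pair.target.start,
            source_end=pair.target.end,
            divergence=nc.divergence,
            chrom_id=nc.chrom_id,
            position=nc.position,
            copy_number=nc.copy_number,
            pair=pair,
            footprint_divergence=nc.footprint_divergence,
        ))
    chroms, truth = plant_numts(
        genome, specs, config.chrom_length, config.seed, gc=0.41
    )
    chrom_by_id = {c.id: c for c in chroms}

    report = screen_primer_set(
        pairs, chroms, genome, config.max_mismatches, config.max_product_length
    )

    verdicts: dict[str, PairVerdict] = {}
    all_profiles: dict[str, dict[str, PeakProfile]] = {}
    for pair in pairs:
        res = report.results[pair.id]
        mt_allele = genome.fetch(pair.target.start, pair.target.end)
        nuclear_alleles = [
            chrom_by_id[a.template_id].fetch(a.region.start, a.region.end)
            for a in res.nuclear_amplicons
        ]
        profiles, numt_fraction, het_total, dh_total, dh_mt = _pair_profiles(
            pair, mt_allele, nuclear_alleles, config
        )
        call_uncut = call_interference(
            profiles["total_uncut"], profiles["mt_uncut"],
            config.abundance_tolerance,
        )
        call_cut = call_interference(
            profiles["total_cut"], profiles["mt_cut"],
            config.abundance_tolerance,
        )
        verdicts[pair.id] = PairVerdict(
            pair_id=pair.id,
            risk_flag=res.risk_flag,
            target_recovered=res.target_recovered,
            n_nuclear_amplicons=len(res.nuclear_amplicons),
            numt_fraction=numt_fraction,
            het_fraction_total=het_total,
            dhplc_total=dh_total,
            dhplc_mt=dh_mt,
            call_uncut=call_uncut,
            call_cut=call_cut,
        )
        all_profiles[pair.id] = profiles

    return PipelineResult(
        config=config,
        pairs=pairs,
        mt_genome=genome,
        chromosomes=chroms,
        truth=truth,
        screen=report,
        verdicts=verdicts,
        profiles=all_profiles,
    )


def _write_tsv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_report_bundle(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA inputs, truth table, screen report and verdicts.

    Output is byte-identical across runs with the same config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = provenance(result.config)
    paths = {
        "provenance": outdir / "provenance.yaml",
        "mt_genome": outdir / "mt_genome.fasta",
        "chromosomes": outdir / "chromosomes.fasta",
        "truth": outdir / "numt_truth.tsv",
        "screen": outdir / "screen_report.tsv",
        "verdicts": outdir / "verdicts.tsv",
    }
    paths["provenance"].write_text(
        yaml.safe_dump({"provenance": meta, "config": result.config.to_dict()},
                       sort_keys=True)
    )
    write_fasta([result.mt_genome], paths["mt_genome"])
    write_fasta(result.chromosomes, paths["chromosomes"])
    _write_tsv(result.truth, paths["truth"], meta)
    _write_tsv(result.screen.to_frame(), paths["screen"], meta)
    _write_tsv(result.verdict_frame(), paths["verdicts"], meta)
    return paths
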