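# Methods

## Problem setting

Human mtDNA is a 16,569-bp circular genome present in hundreds of copies
per cell. Nuclear mitochondrial DNA segments (NUMTs) are ancient insertions
of mtDNA fragments into chromosomes; they are similar but not identical to
the modern mitochondrial sequence. A primer pair designed against mtDNA can
therefore co-amplify one or more NUMT loci. In heteroplasmy screens that
detect *mixtures* of sequences — heteroduplex chromatography, or
mismatch-nuclease digestion followed by size-based fragment detection — a
co-amplified NUMT is indistinguishable from genuine low-level heteroplasmy
unless the total-DNA result is compared against a pure-mtDNA control.

`numtscreen` models the in-silico half of that validation strategy:
(1) predict which primer pairs can amplify nuclear loci at all
(co-amplification *risk*), and (2) predict which of those would actually
distort the fragment readout (*interference*), by simulating the annealing
and cleavage chemistry on explicit sequences.

## Coordinate conventions

All coordinates are 1-based inclusive, on the circular mitochondrial
coordinate system. An origin-spanning region is written `start > end` and
has length `(L - start + 1) + end` with `L = 16569`; e.g. 16344–276 spans
502 bp. Region length is invariant under rotation of the circle. These
conversions live in `catalog` and nowhere else.

## Primer-site search

Binding sites are found by an exhaustive gapless Hamming scan on both
strands (`search.scan_primer`), vectorised as a sliding window over
bit-encoded bases (A=1, C=2, G=4, T=8; an IUPAC code is the union of its
bases; two bases are compatible iff their bit sets intersect). `N` in a
template matches everything by default (configurable). Circular templates
are extended by one primer length minus one so origin-spanning sites are
found exactly once.

Gapless matching is a modelling decision, not a shortcut: over
primer-length windows, NUMTs are co-linear with mtDNA, so an
indel-tolerant aligner adds parameters without adding hits. The default
mismatch budget is 4 (20 % of a 20-mer), enough to populate the
"two or more mismatches" category used in published screens. Per-primer
categories (perfect / one mismatch / ≥2 mismatches) combine into the
six-symbol unordered pair taxonomy (⊚ △ ▴ ▽ ▾ #).

A hit's `start` is the template position of the primer's **5′ end** in
plus-strand coordinates. A PCR product then runs from the forward hit's
start to the reverse hit's start inclusive, which makes a perfectly
matching NUMT product exactly as long as the mitochondrial amplicon — the
property observed for highly matched NUMTs. Convergent hit pairs further
apart than `2 × expected_size + 1000` bp are not reported as amplicons;
this bound stands in for the informal "too far apart to practically
amplify" judgment and is configurable (no published value exists).
The 3′-terminal-match flag is recorded on every hit but not required by
default; `require_three_prime_match=True` restricts pairing to
extension-feasible hits.

## Duplex and cleavage model

A mixed template population (allele sequences with fractions `f_i`,
equal-length and gaplessly alignable in v1) reanneals randomly: ordered
strand pairs (i, j) form with probability `f_i · f_j`, merged over
unordered equivalence. For a biallelic mixture with minor fraction `f`,
total heteroduplex abundance is `2 f (1 − f)` — maximal 0.5 at `f = 0.5`,
strictly increasing on (0, 0.5]. No annealing bias is modelled (the
mass-action assumption).

The mismatch nuclease nicks both strands at the 3′ side of each mismatched
base; the staggered nicks excise the mismatch position, so an amplicon
`[s, e]` with one mismatch at `p` yields double-stranded fragments of
`p − s` and `e − p` bp (139 and 190 for the 330-bp worked case), and `k`
mismatches yield `k + 1` fragments of sizes
`p₁ − s, p₂ − p₁ − 1, …, e − p_k`, summing to `length − k`. Digestion is
complete for heteroduplexes and absent for homoduplexes by default; a
`digestion_efficiency` parameter in [0, 1] leaves the complementary mass
at full length to emulate partial or noisy digestion. All substitution
types cleave equally (no published efficiency spectrum).

### Peak profiles

Abundances are **mass fractions**: a fragment inherits its parent duplex's
abundance scaled by its share of the parent's length, so total signal is
conserved through digestion (and matches an intercalating-dye readout).
Peaks within sizing resolution — `max(2 bp, 5 %)` of the size, a stand-in
for the instrument's unstated resolution — are merged at their
abundance-weighted mean size; peaks below the detectability floor
(default 100 bp, the recommended minimum fragment size for the size-based
detector) are removed from the reported profile but retained in
`raw_peaks` for conservation checks.

### Readout predictions and interference calls

* **Heteroduplex chromatography** (`dhplc_predict`): heteroduplexes are
  reported present when their total abundance reaches
  `2 · 0.05 · 0.95 ≈ 0.095`, the abundance at the technique's empirical
  ~5 % minor-allele floor.
* **Interference** (`call_interference`): total-DNA and pure-mtDNA
  profiles of the same cut state are compared as *peak patterns*. Peaks
  are matched by size within sizing resolution; a peak counts as present
  when its abundance exceeds a tolerance (default 0.01 mass fraction), and
  a peak present in one profile but absent in the other is a difference.
  Abundance shifts of shared peaks are deliberately not differences: the
  assay criterion is the appearance/disappearance of peaks, and under a
  quantitative reading the depletion of the parent peak would flag every
  heteroduplex-forming pair regardless of whether any fragment is
  detectable.

Nuclear products the same length as the mitochondrial amplicon co-anneal
with it in one mixture; off-size products cannot form gapless
heteroduplexes with it and are superimposed as independent full-length
peaks weighted by template share. Heteroduplexes between an off-size
nuclear product and the mtDNA amplicon (which would involve looped-out
ends) are not modelled.

## Synthetic data

The generator replaces external sequence databases and cell DNA:

* `make_mt_genome` — random circular genome, default 16,569 bp at 44 % GC
  (human mtDNA composition). `embed_primer_sites` writes every
  catalogue pair's forward primer and reverse-primer complement at the
  published target coordinates, so all 65 pairs recover their intended
  amplicons on the stand-in. The published catalogues' own overlapping
  footprints disagree at two positions (1045, 15326 — adjacent pairs
  demanding different bases, presumably table typos); the first-written
  base is kept, and recovery is unaffected within the mismatch budget.
* `plant_numts` — copies of mtDNA regions substituted i.i.d. at a
  per-site rate `d ∈ [0, 0.2]`, written onto random 200-kb chromosomes.
  Substitutions are uniform over the three alternative bases
  (transition/transversion ratio 1 — a documented non-biological
  simplification; no indels in v1). A separate `footprint_divergence`
  rate can be applied inside the two primer footprints, allowing dense
  interior divergence on an amplifiable copy. Multi-copy families share
  one mutation realization (identical paralogs, as after segmental
  duplication); the truth table records every copy's coordinates,
  substitution offsets and per-footprint mismatch counts, so every
  quantity the pipeline later infers is checkable against generation-time
  ground truth.
* `make_mixture` — biallelic dilution series over one amplicon, default
  minor fractions {0, 2, 5, 10, 20, 50} %, differing at exactly one
  interior position.

What the generator does **not** emulate: real chromosomal sequence
context, rearranged/partial NUMTs, PCR chimeras and heteroduplex
artifacts, amplification-efficiency competition between templates, and
retention-time physics. Passing end-to-end tests therefore demonstrate the
internal consistency of the screening-and-digestion logic under the stated
chemistry model, not performance on real genomic DNA.

## Pipeline and template fractions

`run_full_screen` chains simulate → screen → digest → compare and emits a
per-pair verdict table. Template fractions in the "total DNA" mixture
come from copy numbers: `mt_copies` (default 200) mtDNA templates against
one template per planted NUMT copy. The true cellular ratio is unknown
and certainly assay-dependent, so it is an explicit swept parameter, not a
calibrated constant. The packaged demonstration uses families of 5–10
copies (NUMT fraction ≈ 2.4–4.8 %), which places heteroduplex abundance
below the chromatographic floor but above the fragment-readout tolerance —
the regime in which only the fragment-based readout can reveal
interference.

The demonstration conditions span the qualitative regimes: an
identical-sequence family (amplifiable but indistinguishable), two lightly
diverged families (detectable fragments), and one heavily diverged family
(d = 0.15) whose fragments fall below the 100-bp floor. Divergence rates
were chosen from the expected substitution counts they imply (≈2–3
substitutions for the light families, ≈40 for the dense one); realized
counts are recorded in the truth table and all tests compare against the
realized, not intended, values.

## Numerical and degenerate-input choices

* Mismatch offsets at an amplicon boundary have no defined cut and raise
  an error; adjacent mismatches produce interior fragments of size 0,
  which are kept in the arithmetic (conservation) but never become peaks.
* Allele fractions must sum to 1 within 1e-9; zero-fraction alleles are
  dropped at annealing.
* Unequal-length alleles in one mixture are rejected
  (`UnsupportedMixtureError`) rather than approximated.
* Peak merging is greedy left-to-right on sorted sizes; ties cannot occur
  with distinct sizes, and the merged representative is the
  abundance-weighted mean.
* Reports are sorted on (pair id, template id, position) and are invariant
  under input-record reordering; all randomness flows from a single
  integer seed through named child streams, making report bundles
  byte-identical across runs.

## Known limitations

* Equal-length gapless duplexes only; indel-bearing NUMTs and looped
  heteroduplexes are out of scope (v1).
* No PCR yield/competition model: a NUMT that amplifies poorly in practice
  is weighted purely by its template copy number here.
* The DHPLC prediction is a single abundance threshold; melting behaviour
  and column temperature are not modelled.
* The brute-force scan is exhaustive by design; at genome scale (hundreds
  of Mb) an indexed search would be needed, but fixture-scale inputs
  (≤ a few hundred kb per template) run in milliseconds.
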