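# Methods

This note documents the models and numeric conventions behind `rgenseq`:
what the simulator assumes, how the caller decides, which parameters matter,
and what the synthetic benchmarks do and do not demonstrate about real data.

## Coordinate conventions

All coordinates are 0-based, half-open, in memory and on disk (BED
convention). For a + strand protospacer occupying [s, s+20) with its PAM on
[s+20, s+23), the blunt-cut **breakpoint coordinate** is s+17 — the first
base 3′ of the cut on the forward strand, 3 bp upstream of the PAM. A
minus-strand site is mirrored: protospacer on [s, s+20) read on the reverse
strand, PAM on [s−3, s), breakpoint s+3. Measured in protospacer
orientation, the distance between the breakpoint and the protospacer/PAM
junction is 3 bp on both strands; this is the "offset law" the benchmarks
verify.

A productive read from the right flank of a cut is a forward-strand read
with its 5′ end at the breakpoint; from the left flank, a reverse-strand
read with its 5′ end at breakpoint − 1. The 5′ end of a reverse alignment
is its **rightmost** aligned reference position; soft clips never shift the
recorded end.

## Library simulation

The simulator emits aligned SAM directly (no FASTQ/aligner round trip), so
the whole pipeline is testable without external tools; read mapping is
upstream of this package's scope.

* **Genome**: i.i.d. bases at a configurable GC fraction (default 0.42,
  mammalian-like). Real genomes have repeats and compositional structure
  that i.i.d. sequence lacks; consequences are discussed under
  *Limitations*.
* **Planting**: protospacer variants at an exact Hamming distance from the
  guide, followed by a PAM drawn from the pattern (default NGG), are
  written into the genome ≥200 bp apart and ≥100 bp from contig ends. An
  exhaustive scan then verifies that no unintended placement exists at
  ≤ `verify_max_mismatches`. The verification ceiling is configurable
  because a random megabase-scale genome *intrinsically* contains a few
  coincidental 5–6-mismatch NGG placements (expected ≈3 per Mb at ≤6
  mismatches); such placements receive no reads and are invisible to the
  caller, so benchmark scenarios verify uniqueness at 3–4 mismatches and
  regenerate the genome if even that fails.
* **Cleavage**: Cas9 is single-turnover — it stays bound after cutting —
  so each template copy is cut at each site at most once, with Hill
  probability p = Cʰ/(Cʰ+Kʰ) (h defaults to 1; the affinity K is the
  concentration of half-maximal cleavage). Per-site uniform variates are
  drawn from a stream keyed by (seed, site index), which couples
  realisations across concentrations: with a shared seed, the copies cut at
  a lower C are a subset of those cut at a higher C, making
  concentration-sweep counts monotone site by site, as occupancy reasoning
  demands.
* **Read emission**: each cleaved molecule offers two flanks; each flank
  yields a read with probability `p7L_ligation_efficiency` (default 0.8).
  With `end_repair=True` all 5′ ends sit exactly at the breakpoint. With
  `end_repair=False` the PAM-distal flank is degraded: its 5′ end recedes
  by a geometric offset (support 0, 1, 2, …; mean `resection_mean`,
  default 5 bp) and receded — i.e. non-blunt — ends ligate with
  probability `nonblunt_ligation_efficiency` (default 0.5). The second
  mechanism is this package's modelling choice: degradation that only
  *moved* ends would leave flank-level coverage balanced, whereas the
  observable consequence of skipping end repair is a depleted distal
  flank; requiring a blunt end for efficient ligation is the minimal
  one-parameter mechanism with that consequence. With the defaults the
  expected retained fraction of distal reads is 1/6 + (5/6)·0.5 ≈ 0.58,
  giving ≈26 % median flank skewness versus <1 % with end repair on.
* **Background**: pre-existing breaks that capture residual first adapter
  are Poisson-scattered uniformly at `background_break_rate` expected ends
  per kb per template copy, each emitting one read in a random orientation.

Determinism: identical `SimConfig` (seed included) reproduces the SAM
byte for byte. Reads whose 5′ end falls outside a contig are dropped and
counted; reads overrunning a contig end are truncated — never emitted
malformed.

## Cut-site calling

1. **Window score**: S(c) = read ends (both strands) in [c−5, c+5),
   window width 10 (even widths keep the two pileup positions, c and c−1,
   centred).
2. **Candidates**: positions with S(c) ≥ `min_score` (default 5) that,
   with `require_bidirectional` (default on), hold ≥1 forward and ≥1
   reverse end in the window — one-sided background spikes are rejected,
   though the filter is toggleable because heavy resection depletes one
   side. A clean cut yields a 9-position run of *equal* scores centred on
   the breakpoint, so runs of consecutive equal-score positions collapse to
   their central position (lower median for even runs) before suppression;
   remaining candidates within one window width of a stronger one are
   suppressed (score descending, tie → leftmost). Collapsing to the run
   centre rather than the run edge is what places the candidate at the
   breakpoint itself — an edge rule would bias every candidate half a
   window leftward and defeat the ±2 bp matching tolerance.
3. **Guide matching**: every protospacer+PAM placement on either strand
   whose implied breakpoint (3 bp upstream of the PAM) lies within
   `position_tolerance` (default 2 bp) of the candidate is scored; among
   placements with a PAM matching the IUPAC pattern and ≤ `max_mismatches`
   (default 7) Hamming mismatches, the winner minimises (mismatches,
   |implied − candidate|, + strand first, leftmost). The reported cut
   position is the placement-implied breakpoint; the reported score is the
   window sum recomputed there. Candidate generation is signature-first —
   an unbiased screen must not assume where sites can be — with
   `enumerate_genome_matches` available as an independent oracle and
   optional prefilter.

Raising `min_score` can only remove sites (outputs are nested), and under
nested subsampling window scores are non-decreasing in the retained
fraction, which is why saturation curves are monotone by construction.

## Diagnostics

* **%skewness** = 100·|L−R|/(L+R) over read ends in [cut−flank, cut) and
  [cut, cut+flank), flank 200 bp — wide enough to catch ends receded by
  `resection_mean` ≤ 20, narrower than the 200-bp planting separation. The
  PAM side is labelled proximal; labelling affects only reporting, since
  the statistic is symmetric. Undefined (flagged, not numeric) when both
  flanks are empty.
* **Productive-read fraction**: percent of mapped ends within ±5 bp of a
  known cut. The 5-bp tolerance is this package's choice.
* **Saturation**: nested subsampling (one uniform per read) at ascending
  fractions, then a full call per fraction. Nesting trades the independent
  subsets a sequencing experiment would draw for an exactly monotone curve,
  a strictly stronger testable property at small scale.
* **Concentration response**: a full simulate→call per concentration with
  shared truth and seed, optionally capped at a fixed `read_budget` to
  emulate constant sequencing depth. The budget is what produces the
  characteristic score dynamics: at low C the few high-affinity sites share
  the depth with background; at intermediate C their occupancy saturates
  and median score peaks; at high C many weak sites enter near the score
  threshold and dilute the fixed depth, pulling the median back down. The
  sweep scenario plants 2 strong / 8 intermediate / 40 weak sites with
  affinities spanning 30–3000 nM because genomes hold far more weak
  near-targets than true targets — the premise behind that decline.
* **Score stats by mismatch**: groups {0–3, 4, 5, 6, 7}; the lowest group
  pools 0–3 mismatches. Sample variance (ddof 1), NaN below two sites;
  log10 variance available for log-axis presentation.

## Set comparison

Sites from multiple inputs merge by single-linkage clustering (|Δpos| ≤
tolerance, default 5 bp, same chromosome; strand ignored — a breakpoint is
a genomic location, the matched strand is annotation). The 5-bp default
covers caller jitter (±2 bp matching tolerance) plus end heterogeneity.
Single linkage merges borderline pairs symmetrically and is the one place
counts can differ from fixed-bin tools. The representative coordinate is
the highest-scoring member's (tie → leftmost). Distinct-mode combination
counts partition the merged rows exactly; intersect mode counts supersets.
Pearson r (and R² = r²) over shared-site scores requires ≥3 shared sites.

## Benchmark problem sizes

The built-in scenarios run on one CPU in seconds: the recovery benchmark
uses a 1-Mb genome, 12 sites (0–6 mismatches, K log-spaced 4–400 nM),
20 000 template copies at 64 nM → ≈220k reads; the replicate pair uses 36
sites on 400 kb with ≥100 expected reads per site; the end-repair pair 12
low-mismatch sites on 200 kb; the concentration sweep 50 sites on 300 kb
with a 1 500-read budget per library. These sizes keep every claimed
regime (thousands-fold pileups, >100 reads/site, budget-limited depth)
while staying small enough for routine testing.

## Limitations

* The i.i.d. genome has no repeats, so mapping ambiguity — the reason for
  the MAPQ ≥ 20 default filter (the alignments here carry MAPQ 60) — is
  never exercised; on real data low-MAPQ pileups in repeats are the main
  false-positive risk this filter addresses.
* No sequencing-error or base-quality model; bulged (insertion/deletion)
  guide alignments are out of scope — matching is pure Hamming plus a
  3-letter IUPAC PAM.
* Background break abundance and residual-adapter carry-over are free
  parameters, not estimates; defaults were chosen to keep background an
  order of magnitude below signal in the recovery scenarios and comparable
  to signal at the low end of the concentration sweep.
* Cleavage is independent across sites and copies; competition for enzyme
  between sites (relevant for pooled guides at limiting RGEN) is not
  modelled.
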