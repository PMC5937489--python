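# Methods

This note documents the models, conventions and numerical choices behind
`pseudoattb`, and what the synthetic benchmark does and does not establish.

## The att-site model

A serine-integrase attachment site is represented as a window anchored on
the crossover core: `arm_left` nt, the 2 nt core (GT for ΦBT1), `arm_right`
nt.  All cross-sequence comparison superposes the cores and is strictly
gap-free — observed pseudo-attB integration is precise, with no insertions
or deletions at the target, and the published site alignments are likewise
ungapped and core-centred.  Consequences:

* **Coordinates.** Reports are 1-based inclusive (internally 0-based
  half-open).  A site's position is the forward-strand coordinate of the
  core anchor base: the G of the GT for plus-strand sites, the pairing C
  for minus-strand sites (where the forward strand reads AC).  BED output
  is 0-based half-open; every file header states its convention.
* **Identity statistic.** Position-wise equality counts over three nested
  spans centred on the core: the full canonical attB (73 bp for ΦBT1), the
  minimal attB (36 bp = 17+2+17) and the attB–attP crossover (9 bp).
  Counts are the primary statistic; integer percentages use round-half-up
  and are cosmetic (published percentages are not internally consistent
  between 35/73→48% and 19/36→52%, so no rounding convention can match all
  of them; ours matches the 73 bp column).  Non-ACGT characters never
  match.  Because the spans are nested and both cores are GT,
  `count_full ≥ count_minimal ≥ count_crossover ≥ 2` always holds.
* **Arm splits.** The geometry is configuration, not constants.  The
  machine-readable record of ΦBT1's exact 73 bp arm split and crossover
  split is figure-only, so defaults are 35+2+36 (full) and 4+2+3
  (crossover); any values can be supplied in the TOML config, keeping the
  model correct for other integrases.
* **Canonical sequences.** The shipped canonical attB/attP pair is a
  deterministic *synthetic stand-in* with the correct geometry
  (`synthetic_canonical_att`, provenance-labelled).  Analyses of real data
  must supply transcribed sequences via the `[canonical]` config section.
* **Products.** `reconstruct_att_products` implements the arm-exchange
  rule attL = B_L+GT+P_R, attR = P_L+GT+B_R.  Total length is conserved:
  each input contributes its copy of the core to one product.  A missing
  GT core in either input is an error — matching cores are mechanistically
  required for strand exchange.

## Junction detection

Transformant assemblies are compared with the host reference and plasmid by
exact k-mer anchoring (default k = 21).  Every contig k-mer is labelled
reference / plasmid / neither; a host→plasmid→host run structure is one
insertion event.  The reference coordinate of the shared core follows from
the flanking anchors on each side; the two independent estimates must
agree for the event to be flagged `precise`.

* When attP shares bases with the host flank immediately beyond the core
  (junction microhomology), anchors overextend and the two estimates
  straddle the true core by up to the microhomology length.  The ambiguity
  interval is resolved at the position carrying the core motif (GT on plus,
  AC on minus), ties broken toward the lower coordinate; such events remain
  `precise`.  Estimates separated the other way (lost host sequence) or by
  more than 5 nt are emitted with `precise=false`.
* Exact matching only: the benchmark assemblies are error-free and the
  emulated study's calls came from curated assemblies.  Mismatch-tolerant
  anchoring is a deliberate non-feature.
* Contig orientation is normalized by a strided anchor vote; reference and
  plasmid k-mers occurring in both (or repeated in the reference) are
  masked before detection.
* Collation groups events by exact (position, strand), orders site ids by
  ascending position, and reports per-site transformation-reaction
  diversity (a sibling-colony diagnostic) without discarding any event.
  Multi-insertion contigs yield multiple events.

## Motif model and exact p-values

Observed site windows are already aligned by their GT core, so the motif is
the column profile of the windows — no EM-style discovery is performed (a
deliberate divergence from seeded motif-discovery workflows; the alignment
step those tools perform is a no-op here).  Defaults: width 34 (one column
trimmed from each end of the 36 nt windows; core at motif positions 17–18,
i.e. offsets −16…+16), pseudocount 0.5 distributed by the background,
background = mononucleotide frequencies of the scanned genome (these
actinomycete genomes are strongly GC-rich; a uniform background is a
config option).

Log-odds scores (bits) are discretized to bins of 1/1000 bit and the exact
null score distribution is obtained by convolving per-column bin
distributions across positions (dynamic programming over at most a few
hundred thousand bins).  P-values are therefore exact for the discretized
score and conservative to ±1 bin.  The scanner evaluates every position on
both strands, wraps circular genomes across the origin, and does not
require the core GT to match (an optional `require_core` flag restricts
hits, since every *observed* integration site carries the core).  The
default reporting threshold is p ≤ 1e−8, the stringency used for
genome-wide pseudo-attB prediction in the emulated study.

## Richness estimation

Sites are treated as species and integration events as sampled individuals
(abundance framework, since the data are per-site event counts).  Provided,
all labelled, none privileged:

* **Rarefaction** (interpolation): `E[S_n] = Σ_i 1 − C(N−x_i, n)/C(N, n)`,
  computed with log-gamma binomial coefficients; reported to 2 decimals.
* **Chao1**: classic `S_obs + F1²/(2F2)` and bias-corrected
  `S_obs + F1(F1−1)/(2(F2+1))`; with no doubletons the classic form
  switches to bias-corrected with a warning.
* **Asymptote fit**: least squares on the rarefaction curve.  The default
  model is exponential saturation `S(n) = S_max(1 − e^(−n/B))` — the exact
  form of expected richness under uniform multinomial sampling from a
  finite pool, and the model whose fits we could validate by parameter
  recovery (27 draws from 40 equally weighted sites, 500 replicates:
  median fitted S_max ≈ 40.8).  A Michaelis–Menten alternative
  `S_max·n/(B+n)` is available but overshoots badly on curves of this
  shape (median ≈ 71 in the same experiment) and is not the default.
  Start values are analytic (terminal richness ×1.5; B from the initial
  slope), S_max is bounded below by the observed terminal richness, and
  tolerances are fixed, so the fit is deterministic.

On the published 27-event abundance vector the three projections are 75.25
(classic Chao1), 54.0 (bias-corrected Chao1) and ≈38.6 (exponential
asymptote).  The published projection of 40 total sites came from an
unspecified rarefaction procedure; the exponential asymptote is the only
one of the three that lands near it, but with N = 27 events all such
projections carry large sampling error (10th–90th percentile roughly
29–62 in the recovery experiment) and should be read as order-of-magnitude
statements.

## The synthetic benchmark

`synthetic_data` emulates the structure of a pseudo-attB mapping
experiment at desk scale: a 200 kb circular host (i.i.d. bases at GC 0.68,
standing in for a 9.3 Mb *Nocardia* chromosome), 20 planted sites whose
minimal-attB identities span 12/36–22/36 (the observed pseudo-attB range),
a 6 kb attP-bearing circular plasmid, and 27 single-insertion transformants
drawn from 14 independent reactions — the emulated study's sampling depth.
Planting copies the canonical minimal attB and mutates an exact seeded
subset of the 34 non-core positions (the core GT is never touched); site
strand is Bernoulli(0.5); accidental exact canonical copies in the
background are removed.  Site choice is weighted (uniform by default;
identity-proportional or explicit weights available) — the emulated study
observed site preference but quantified no model for it, so the weights
are a simulation knob, not an estimate.

What the benchmark does **not** emulate: sequencing error, read-level data,
assembly fragmentation, genomic repeats, compositional heterogeneity, or
replicative/multi-copy plasmids.  Passing tests therefore establish the
correctness of the arithmetic and the detection logic on clean assemblies,
not robustness to noisy real-world data; on real assemblies the exact-match
anchoring requires locally error-free junction neighbourhoods
(± ~25 nt).

Determinism: a fixed `SimConfig` yields byte-identical genomes and truth
tables (seeded generators with fixed stream splitting for host, plasmid
and transformant sampling).

## Published-count stand-ins

The supplementary per-site *sequences* of the emulated study exist only in
figure form.  Where tests and the acceptance script reproduce published
per-site identity **counts** (e.g. the preferred *N. uniformis* site at
35/73 and 22/36, or the minimum crossover overlap of 2), they do so on
*synthetic stand-in windows* constructed — by an independent shell-placement
path — to carry exactly the published nested identity structure, then
scored through the normal pipeline.  This validates the scoring arithmetic
against planted truth with the published values as targets; it does not
verify the study's actual sequences.

## Problem sizes

Default test and acceptance workloads: 50–200 kb hosts, 10–20 sites,
25–100 transformants, 100k-replicate resampling checks and 500-replicate
recovery experiments — sizes chosen so the full suite runs in seconds
while keeping every Monte-Carlo check's 3σ band meaningful.
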