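# Methods

`cuparray` models the structure and dynamics of the *CUP1* tandem array of
*Saccharomyces cerevisiae*: a head-to-tail repeat of a 1.2–2.0 kb unit that
carries the CUP1 metallothionein gene (61 aa, encoded inside the noncoding
RNA gene RUF5 on the opposite strand), flanked centromere-proximally by CIC1
and distally by RSC30, with one ARS per repeat unit. This note records the
model choices, the parameters that matter, what the synthetic generator does
and does not emulate, and the numerical conventions.

## Junction mapping

A repeat junction is decomposed by extending its start maximally against the
centromere-distal flanking reference and its end against the
centromere-proximal reference. The overlap of the two matched spans on the
junction is microhomology; an unmatched middle is a junction insertion. The
accounting identity

    prefix + suffix − microhomology + |insertion| = junction length

holds for every mappable junction. Junctions whose microhomology is at most
3 bp are classified *nonhomologous* (the signature of nonhomologous
end-joining); longer shared homology is *homology-mediated*.

Mismatch policy (configurable, `MismatchPolicy`):

* an extension must begin with a 12 bp exact anchor (`seed_len`);
* one isolated mismatch is tolerated only when flanked by ≥ 5 exact matches
  on both sides; two adjacent mismatches terminate the extension;
* extensions always end on a matching base.

Tie-breaking is deterministic: among equally long prefix matches the one
ending closest to the distal reference's end wins; the mirror rule applies
to suffixes. If neither side can be anchored the junction is reported
*unmappable* rather than raising. The rationale for tolerating isolated
mismatches is that real repeats differ from their flanks by occasional SNPs
(about 0.4–0.7% flank divergence), which must not truncate an otherwise
unambiguous match.

## Repeat-unit inference

The unit length of an array is the period `p` in `[min_p, max_p]` (defaults
800–2500 bp) maximizing the self-match fraction
`mean(seq[i] == seq[i+p])`, accepted only when the fraction reaches
`match_threshold` (default 0.95). Because sampling noise under divergence
can let a harmonic (2p, 3p, …) outscore the fundamental by a hair, the
smallest scanned divisor of the winning period that also clears the
threshold is preferred. Inferred lengths are binned to repeat types by
nearest exact unit length within ±60 bp; hits in two bins (possible for the
1998 bp Type 1 vs the 1900 bp Type 4) report "ambiguous".

## Copy number

EcoRI does not cut within a repeat, so the probe-hybridizing fragment is the
single-copy fragment plus `(n−1)` units:

    n = round((L_frag − L_single)/unit + 1),  round-half-to-even

with `L_single = 5.2 kb` by default. Rounding half-to-even is applied to the
full expression; the 18.7 kb Type 2 fragment sits exactly on the 8.5-copy
boundary and resolves to 8. The estimator refuses fragments more than
0.5 kb below the single-copy size (gel-sizing tolerance). The single-copy
constant is exposed per repeat type (`per_type_single_copy_kb` in the
report runner) because the flanking EcoRI distances genuinely differ between
types: with the shared 5.2 kb constant two of the three Type 3 survey rows
come out one copy low, and a Type 3 constant of 4.4 kb reconciles all three.
We do not claim 4.4 kb as a measured value — it is the constant jointly
consistent with the three printed Type 3 rows.

Depth-based copy number is mean depth over the repeat interval divided by
the median depth over user-chosen single-copy baseline intervals, with a
warning when the baseline median is below 5× (integer rounding becomes
unreliable).

The cut-position convention within GAATTC is G^AATTC; it cannot affect
fragment lengths at kb resolution but is fixed for determinism.

## In-silico PCR

Primer binding is exact-match over the full primer (minimum 15 bases): the
assays modelled are presence/absence, not thermodynamic. All convergent
site pairs with product length ≤ `max_len` (default 3000 bp) are reported.
The two assays:

* *outward pair* within CUP1 (5′ ends 40 bp apart): silent on a single-copy
  locus; on an n-copy array each junction yields one product of
  `unit − 40` bp. When counting one product class per junction the cap is
  set below two units, since a cap above `2×unit − 40` would also admit
  double-junction products that a gel would show as a faint ladder.
* *flanking pair* (CIC1 → RSC30): a single 2.7 kb product on a single-copy
  locus; on arrays the product would exceed the cap, so the assay is a
  single-copy diagnostic.

## Array dynamics

Events act on unit-count abstractions (`ArrayState`, one marker flag per
unit) for population-scale work, with full sequence realization available
for any single event:

* `nhej_duplicate` — two replication-fork breaks, one on each side of CUP1,
  rejoined crosswise. The duplication product carries the inter-break
  segment twice plus any junction insertion; the reciprocal sister product
  deletes the segment. Total sequence length is conserved up to the
  inserted bases.
* `unequal_crossover` — misalignment by `k` units between sister arrays;
  products gain and lose `k` units reciprocally; unit and marker totals are
  conserved. The crossover boundary is uniform over the feasible range
  unless specified.
* `contract_array` — pop-out (with the excised circle reported) or
  single-strand annealing; the marker is lost iff a marked unit lies in the
  excised span.

The default event-size distribution is uniform over feasible `k`: no
empirical distribution of units gained/lost per event is available, so
uniform is the declared, configurable default, and observed single-copy
fractions from marker-loss screens remain calibration data rather than
hard-coded targets. In `simulate_marker_loss` the excision span is by
default drawn conditional on containing the marked unit, because a 5-FOA
screen only detects marker-loss events; under that convention the expected
single-copy fraction with uniform `k` on `1..n−1` is exactly
`P(k = n−1) = 1/(n−1)` (1/13 for a 14-unit array). Unconditional span
placement is available (`condition_on_marker=False`). Break-induced
replication variants are not simulated.

## Fluctuation analysis

Cultures grow by discrete doublings from an inoculum of 10³ cells to a
target final population (default 2×10⁷, the cell density of a saturated
5 mL culture); the final generation is partial so the target is hit
exactly. Every division yields a mutant with probability μ (binomial draws
per generation) and mutant lineages grow at the culture rate, producing the
heavy-tailed jackpot distribution. Plating efficiency and phenotypic lag
are assumed perfect.

The Lea–Coulson method of the median solves `r̃/m − ln m = 1.24` for the
expected mutations per culture `m`, by bisection in log-space on
`m ∈ [10⁻⁶, 10⁹]` to 10⁻⁹ relative tolerance; the per-division rate is
`m / N_final`. A zero median is reported as "below detection" rather than a
number. Estimator recovery is verified by simulation: over 200 replicates
of 60 cultures at μ = 1.7×10⁻⁵ the median estimate falls within a factor of
two of truth.

Composite rates multiply a base rate by an event fraction `k/n` from a
secondary screen, with a Clopper–Pearson 95% interval on `k/n` propagated
linearly onto the rate.

## Regressions

Ordinary least squares with the two-sided zero-slope t test (n−2 df);
OLS rather than rank correlation because the quantities compared are
reported as R² from linear fits. The censored copper value of the
single-copy strain ("<0.1 mM") is included at its bound 0.1 when the
all-strain regression is requested; this is an explicit, flagged assumption
(`censored_at_bound`), not a claim about how the original analysis handled
it.

## Synthetic data: what it emulates, and what it does not

The generator stands in for strains whose array sequences are not publicly
retrievable. `build_single_locus` draws a random 5.6 kb sequence and
imposes the locus grammar: CIC1 (1.1 kb), a 150 bp intergenic region, RUF5
(1.08 kb) containing the 186 bp CUP1 ORF on the opposite strand, an ARS
overlapping RUF5's 3′ end, a 70 bp intergenic region, RSC30 (2.6 kb), and
flanking EcoRI sites placed so the probe fragment is exactly 5200 bp, with
no internal GAATTC. Gene lengths not individually published are
configuration, chosen so every breakpoint assignment is realizable and the
flanking-primer product is 2.7 kb.

Per-type breakpoints are declared configuration, not the original
coordinates: proximal breaks fall in the CIC1–RUF5 intergenic region
(Types 1, 2, 3, 5) or within CIC1 (Type 4); distal breaks fall within the
RSC30-derived sequence (Types 1, 2, 4, 5) or the RUF5–RSC30 intergenic
region (Type 3). Placing the Type 2 and 5 distal breaks in the 70 bp
intergenic region as well is geometrically impossible on a shared locus:
with proximal breaks confined to a 150 bp window, intergenic-to-intergenic
distances span at most ~220 bp, while the Type 2/3/5 unit lengths spread
over 600 bp. Exact unit lengths are 1998 bp for Type 1 and configured
defaults 1800/1200/1900/1600 bp for Types 2–5 (only 0.1 kb-precision sizes
are published).

The bases flanking every configured breakpoint are deterministically fixed
so that matched extensions stop exactly at the breaks (the boundary base
and its neighbour mismatch the junction's continuation), making the truth
labels exact for every seed rather than only with high probability.

Arrays are realized as one NHEJ duplication followed by `n−2`
unequal-crossover expansions (event log included). Divergence applies
substitutions only — 0.7% over the proximal 600 bp flank, 0.4% over the
distal flank, 0.5% within repeats — because divergence between the
sequenced strains is quantified as percent mismatch; indels are not
modelled except for explicit homopolymer-expansion junction insertions in
the junction-case generator (emulating the Type 1 junction's T-tract, seven
bases longer in the repeat than in either flank). Substitutions that would
mint a new EcoRI site inside the probe fragment are reverted, preserving
the no-internal-site property of the real arrays. Depth tracks are
independent Poisson draws per base on the single-copy reference, scaled by
`n` over the repeat interval — no read-length correlation, GC bias,
mappability structure or sequencing error.

Consequently, passing tests show that the *inference logic* is correct
under the stated noise model; they do not show robustness to indels,
rearranged or mixed-type arrays (9 of 66 surveyed multi-copy strains carry
more than one repeat type), alignment artefacts, or real library biases.

## Problem sizes and determinism

Test and verification workloads use 5-copy arrays for mechanism round
trips, up to 18 copies for pipeline recovery, 500 labelled junction cases
for oracle equivalence, 10⁴ crossover events for conservation checks, and
200×60 cultures for estimator recovery — sizes at which every check runs in
seconds while remaining statistically meaningful. All randomness flows
through explicit integer seeds (numpy `default_rng`); identical seed and
configuration reproduce every sequence and truth log byte-for-byte.

## Known limitations

* The shared 5.2 kb single-copy constant under-calls the two larger Type 3
  arrays by one copy (see Copy number above).
* The regression of deep-sequencing vs Southern copy number over the
  printed, integer-rounded survey table gives R² = 0.769; analyses computed
  from unrounded depth estimates would differ slightly.
* `map_junction` performs a single-gap decomposition; it is not a general
  gapped aligner and does not call junctions from raw reads.
* Marker-loss simulation treats each detected event independently; clonal
  expansion of early events within a culture (jackpots) is modelled in the
  fluctuation module, not in the screen tally.
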