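# cuparray

Analyses of *CUP1* tandem arrays in budding yeast: junction breakpoint and
microhomology mapping, repeat-unit and copy-number inference, in-silico
restriction and PCR assays, a mechanistic simulator of array genesis and
contraction, and Luria–Delbrück fluctuation analysis.

## The problem

Most natural isolates of *Saccharomyces cerevisiae* carry the
copper-binding metallothionein gene *CUP1* as a head-to-tail tandem array
of a 1.2–2.0 kb unit; copy number (1 to ~18) sets copper resistance. Two
questions drive the analyses here:

* **How did the array arise from a single-copy locus?** The junction
  between adjacent repeats preserves the founding event. Matching the
  junction against the two flanking references partitions it into a
  distal-derived prefix, a proximal-derived suffix, shared bases
  (microhomology) and bases derived from neither (insertions), under the
  identity `prefix + suffix − microhomology + |insertion| = junction
  length`. Microhomology ≤ 3 bp marks nonhomologous end-joining — the
  inferred genesis mechanism — as opposed to homology-mediated routes.
* **How big is the array, and how fast does it change?** EcoRI does not
  cut inside a repeat, so the probe fragment grows one unit per copy:
  `n = round((L_frag − L_single)/unit + 1)` with `L_single = 5.2` kb.
  Contraction rates come from fluctuation analysis: the Lea–Coulson method
  of the median solves `r̃/m − ln m = 1.24` for the mutations per culture
  `m`, giving the per-division rate `m / N_final`; the single-copy
  reversion rate is the marker-loss rate scaled by the fraction of
  screened derivatives that collapsed to one copy.

Because the study strains' array sequences are not publicly retrievable,
the package ships a deterministic synthetic-data generator (single-copy
locus, typed arrays with truth logs, labelled junction cases, depth
tracks) so every stage is testable end to end.

## Worked example

The one-shot survey report recomputes every desk-scale quantity from the
packaged 14-strain table:

```
$ cuparray survey-report
CUP1 array survey report
========================================

Copy number from EcoRI fragment size:
  S288c       30.8 kb -> 14 copies (Southern 14)
  W303-1A     31.3 kb -> 14 copies (Southern 14)
  YJM189      23.3 kb -> 11 copies (Southern 11)
  YJM972      18.7 kb ->  8 copies (Southern 8)
  YJM996      25.4 kb -> 12 copies (Southern 12)
  YJM789      11.6 kb ->  6 copies (Southern 7)  (differs from Southern)
  YJM693      19.3 kb -> 13 copies (Southern 13)
  YJM1549     24.4 kb -> 17 copies (Southern 18)  (differs from Southern)
  YJM271      20.7 kb ->  9 copies (Southern 9)
  YJM1307     15.5 kb ->  6 copies (Southern 6)
  YJM456      19.8 kb -> 10 copies (Southern 10)
  YJM969       8.5 kb ->  3 copies (Southern 3)
  YJM978       6.5 kb ->  2 copies (Southern 2)

Regressions:
  southern_vs_deepseq: R^2 = 0.77, p = 0.00086, n = 10
  copies_vs_copper_diploid: R^2 = 0.52, p = 0.0184, n = 10
  copies_vs_copper_all: R^2 = 0.64, p = 0.000608, n = 14

Composite single-copy reversion rate: (6/135) x 1.7e-05 = 7.6e-07/division (95% CI 2.8e-07-1.6e-06)
```

Reading the output: the shared 5.2 kb single-copy fragment constant
reproduces the Southern copy number for 11 of 13 multi-copy strains; the
two Type 3 strains it under-calls by one copy reflect type-specific
flanking EcoRI distances (passing `per_type_single_copy_kb={3: 4.4}` to
`run_survey_analyses` reconciles all three Type 3 rows). Copy number
correlates across the two assays (R² ≈ 0.77 on the integer-rounded table)
and with the inhibitory copper concentration (R² = 0.52 over the ten
diploids; 0.64 over all fourteen strains with the censored "<0.1 mM" value
at its bound). A 14-copy array loses its internal URA3 marker at
1.7×10⁻⁵/division, and 6 of 135 such losses collapse the array to a single
copy, giving a single-copy reversion rate of 7.6×10⁻⁷/division.

Other subcommands expose each stage: `generate`, `map-junction`, `digest`,
`pcr`, `copies`, `simulate-events`, `fluctuation`, `correlate` — see
`cuparray --help`. The same functionality is available as a library, e.g.:

```python
from cuparray import generate_array_strain, infer_unit_length, ZERO_DIVERGENCE

strain = generate_array_strain(type_id=5, n=10, seed=3, divergence=ZERO_DIVERGENCE)
span = strain.truth.repeat_span
print(infer_unit_length(strain.sequence[span[0]:span[1]]).unit_len)  # 1600
```

## Layout

```
src/cuparray/
  locus_model.py        domain types, coordinates, FASTA/GFF3/CSV I/O
  junction_analysis.py  junction mapping, unit inference, type binning
  array_metrics.py      digests, copy-number estimators, in-silico PCR
  array_dynamics.py     NHEJ duplication, unequal crossover, marker loss
  fluctuation.py        culture simulation, method of the median
  assoc_stats.py        survey regressions
  synthetic_data.py     generator + truth logs
  cli_reporting.py      CLI and the one-shot survey report
docs/methods.md         model assumptions, parameters, limitations
```
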