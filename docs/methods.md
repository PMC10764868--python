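# Methods and design notes

## The measurement model

Each allele of each panel locus is a tagged allele-specific amplicon whose
tag–probe duplex dissociates at a calibrated melting temperature in one
fluorescence channel. The simulator renders a channel's fluorescence as a
sum of two-state dissociations:

    F(T) = Σ_i  a_i · σ((Tm_i − T) / w_i)  +  c + b·(T − T_min)  +  ε(T)

where σ is the logistic function, `a_i` the component amplitude, `w_i` the
transition width, `c`/`b` a linear baseline and ε additive i.i.d. Gaussian
noise. The negative derivative −dF/dT of an isolated component is symmetric
with its maximum exactly at `Tm_i`, which is what peak calling exploits.
This is a deliberate idealisation: real melt peaks are slightly asymmetric
and amplitude depends on amplification efficiency, but peak *position* —
the quantity the decoder uses — is captured.

Amplitude rule: a homozygous/homoplasmic allele contributes `a = 1`, each
allele of a heterozygote or heteroplasmy `a = 0.5` (each allele supplies
half the template). Published melt figures do not tabulate peak heights, so
absolute amplitude realism is not a goal; optional per-channel scale
factors (`SimulationParams.channel_scale`) emulate unequal probe amounts in
the reaction mix.

### Defaults and why

| parameter | default | rationale |
| --- | --- | --- |
| temperature grid | 30–70 °C, 0.1 °C steps (401 points) | the instrument ramps 30→70 °C acquiring continuously; a fixed uniform grid is the software contract, and 0.1 °C is well below the smallest coordinate gap |
| transition width `w` | 0.5 °C | gives a derivative FWHM ≈ 1.76 °C, comfortably resolving the minimum within-channel gap of 2.4 °C |
| noise sd | 0.005 (relative units) | a visually clean but non-trivial trace; ~2 % of a homozygous derivative peak height (0.5) |
| baseline slope | −0.002 units/°C | mild fluorescence loss with temperature, as real traces show |
| Tm match tolerance | ±1.0 °C | less than half the smallest within-channel gap (2.4 °C in FAM), so tolerance windows are pairwise disjoint |

## Peak calling

1. **Derivative.** A Savitzky–Golay local-quadratic fit over a 0.5 °C
   window, evaluated at its first derivative (`deriv=1`). This is the
   least-squares analogue of "smooth, then central-difference", chosen
   because the combined convolution kernel has a smaller L2 norm, i.e.
   less noise amplification, for the same window.
2. **Noise floor.** The point-noise scale of the raw trace is estimated
   from the lower quartile of successive absolute differences
   (|ΔF| ~ HalfNormal(σ√2), whose 25th percentile is 0.3186·σ√2). The
   quartile, unlike the median, stays noise-dominated even when melting
   transitions cover most of the ramp, as they do in the seven-peak FAM
   channel. Propagating σ through the derivative kernel's L2 norm gives the
   derivative noise sd; the absolute peak floor is 5× that, with a small
   fixed floor of 1e-3 units/°C to reject numerical ripple on noiseless
   synthetic traces.
3. **Baseline.** Peak heights are measured above the quiet between-peak
   level: provisional peaks (relative to a 10th-percentile reference) are
   masked with their ±1.5 °C neighbourhoods and the baseline is the median
   of what remains; if nearly everything is masked (a peakless noise trace
   masks itself), the global median is used, which is then exactly the
   noise level. A single global median is *not* usable directly: on crowded
   channels more than half the grid sits on transition shoulders.
4. **Detection.** Local maxima at least 1.5 °C apart whose height exceeds
   both 25 % of the channel's maximum height and the absolute floor;
   grid-boundary points are excluded. Each peak's Tm is refined by the
   vertex of the parabola through the maximum and its two neighbours
   (sub-grid accuracy: ≤ 0.2 °C error for isolated transitions of width
   ≤ 1 °C, tested).

Both thresholds are deliberately simple and published as configurable
defaults; instrument software keeps its own undocumented equivalents, so
these constitute this package's explicit contract.

## Decoding

A peak is assigned to the nearest coordinate of its own channel within the
±1.0 °C tolerance; in a validated panel the windows are disjoint, so
assignment is unambiguous. Two peaks competing for one coordinate keep the
closer one and flag the sample. Per-locus calls follow from the allele
presence pattern: wild only / both / mutant only / neither →
WW / WM / MM / no-call for diploid loci, and wild-homoplasmic /
heteroplasmic / mutant-homoplasmic / no-call for mitochondrial loci.
Decisions recorded here:

- **no-call vs conflict.** Both alleles absent is a `no_call` and a QC
  failure — in a working multiplex every locus emits at least one allele
  peak — rather than silently "wild". Competing peaks do not change the
  call; they flag the sample.
- **Heteroplasmy** is reported, not suppressed: the assay can physically
  show both mitochondrial peaks. It is QC-flagged because the validation
  cohort contained only homoplasmic states, so a heteroplasmic call in
  routine use deserves review.
- The HEX 48 °C wild/mutant split is re-checked on decoder output
  (`hex_threshold_check`); it can only fail with a mis-specified panel.

## Cohort statistics

- Gene positivity = samples with ≥ 1 mutant allele in the gene; compound
  heterozygote = two different heterozygous sites in one gene; overall
  carriers deduplicate samples across genes (the bundled fixture contains
  one patient carrying both the *SLC26A4* compound heterozygote and
  homoplasmic m.1555A>G, so 34 + 15 + 2 − 1 = 50 carriers).
- Allele frequency: (het + 2·hom)/2n for diploid sites; carriers/n for
  mitochondrial sites (haploid bookkeeping). Heterozygotes of different
  genes are counted separately per site.
- χ² comparisons are Pearson on 2×2 tables without continuity correction,
  df = 1. External cohorts publish rounded rates, not counts; the external
  numerator is reconstructed as round(rate × denominator), with the
  denominator doubled (patients → alleles) for allele-basis comparisons at
  diploid loci. Reconstructed statistics therefore match published ones
  only to the precision the published rounding permits.
- Cohen's kappa is pooled over all (sample, locus) labels. Total observed
  agreement returns κ = 1 even when only one category occurs (the
  chance-corrected formula is 0/0 there, and "complete concordance" is the
  scientifically meaningful answer). The p-value uses the large-sample
  standard error under the null of chance agreement; p < 0.001 is rendered
  as "<0.001" in reports.

## What the simulator does and does not establish

The synthetic cohort generators reproduce the *study conditions*: the
fixture replays the 116-patient validation cohort genotype-for-genotype,
and the random sampler draws loci independently under Hardy–Weinberg at the
observed allele frequencies. Traces place ideal two-state peaks at the
calibrated coordinates. Passing tests therefore demonstrate that the
decoding geometry, thresholds and bookkeeping are correct and
noise-robust under the stated noise model — they do not demonstrate
robustness to effects the model omits: primer cross-reactivity, amplitude
variation between loci, Tm drift with salt/instrument calibration, peak
asymmetry, or alleles outside the panel (e.g. a c.35insG carrier is
invisible to the assay and to the simulator alike). Problem sizes used by
the test suite — 27 single-class round trips, 500 noisy samples, the
116-sample fixture — are the package's chosen verification scale.

## Numerical choices and degenerate inputs

- Grids must be strictly increasing; traces shorter than 5 points are
  rejected; the Savitzky–Golay window is clipped to an odd length ≥ 5 and
  ≤ the trace length.
- Parabolic refinement is clipped to ±½ grid step and falls back to the
  grid point when the three-point stencil is not concave.
- Peaks are returned sorted by descending Tm; downstream decoding is
  order-independent (tested by permutation).
- Empty cohorts summarise to zero counts with frequencies reported as
  not-available rather than dividing by zero.
- External-rate χ² reconstruction requires positive margins; degenerate
  tables raise instead of returning NaN.

## Known limitations

- Tm values are taken from panel calibration; the package does not predict
  Tm from sequence thermodynamics, and the tag/ARMS sequence checks verify
  declared design properties rather than inferring them.
- Merged peaks closer than the derivative FWHM are not deconvolved; the
  bundled panel's 2.4 °C minimum gap avoids the regime, but a custom panel
  with tighter spacing would need the multi-component fitting this package
  deliberately omits.
- The melt-curve CSV dialect is this package's own long format (with a
  column map for renamed headers); instrument-native binary exports are out
  of scope.
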