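# Methods

This note documents the models, parameter choices and numerical conventions
behind `cytoabc`, and what the synthetic-data tests do and do not establish
about real instrument data.

## Bead calibration

Quantitative cytometry converts fluorescence to absolute antigen density
using microspheres with lot-assigned antibody-binding capacities (ABC
units). We fit ordinary least squares to the per-population
(log10 median MFI, log10 assigned ABC) points:

    log10 ABC = a + b · log10 MFI

This log–log-linear form is the convention of quantitation-bead vendors;
with the simulator's power-law response `MFI = g · ABC^e` it is exact, and
the fitted `b` equals `1/e` (exposed as `response_exponent = 1/b = e`).
Conversions outside the bead anchor range extend the line but carry an
extrapolation flag — with the default lot (anchors at 0.8, 1.6, 3.2,
6.4 × 10⁵ ABC) basophils (~7×10⁴ ABC) sit below the lowest anchor and
always exercise this path. A blank bead population, when present, only
estimates background MFI; subtraction is off by default and switchable,
since standard workflows differ on this point. Unlabeled bead data are
partitioned by deterministic 1-D k-means on log MFI (populations are
designed to be well separated); non-monotone medians versus assigned ABC
abort calibration as corrupted beads.

## Gating

Manual gate placement is replaced with density-valley thresholds: for each
channel, a binned kernel-density estimate of log10 intensity (1024 bins,
bandwidth 0.05 log10 units) is scanned for modes; the positivity cutoff is
the deepest point between the two largest modes (the centre of the flat run
when the valley is a plateau of zeros — any point of such a plateau is a
minimum, and the centre is the symmetric, stable choice). Channels gated
hi/lo (CD16, CD56) receive a secondary cutoff from the next valley.
Unimodal channels are flagged and cut at the 0.99 quantile with a warning;
when the expected number of modes is not resolvable the fallback is
midpoints between 1-D k-means centers. Events exactly at a cutoff classify
negative/lo.

Subset definitions transcribe the 18 PBMC phenotypes of the panel. The two
NK rows additionally carry CD11c⁻/CD14⁻/CD123⁻ — negations the original
sequential gating implies — so that every pair of definitions is logically
disjoint; disjointness is checked at load time and overlap on actual events
is an error, never silently resolved. Counting beads are recognised first
(bright in CD3 *and* CD19, a combination no cell shows), then low-FSC
debris is removed. Samples containing beads use a two-pass threshold
resolution (beads removed before cutoff placement) because bead
fluorescence would otherwise add a spurious mode to every channel.

The bimodal CD52 split on naïve B cells and pDCs cuts at the valley between
the two largest CD52 modes and reports a valley-depth bimodality score,
`1 − valley density / min(mode heights)`, flagged bimodal above 0.3. This
plays the role of a dip statistic; it is deterministic and directly
reflects the quantity the split relies on.

## Quantitation

Per subset we take the *median* MFI and convert that single number through
the curve ("convert the median"); for a strictly monotone curve this equals
the median of per-event conversions and mirrors the standard workflow.
Donor aggregation is an unweighted arithmetic mean and SD. Entries with
fewer than 50 events are kept but marked unreliable and excluded from
aggregates. Hierarchies are per-donor descending-ABC orderings with
alphabetical tie-breaks; only the extremes (memory B highest lymphoid,
basophils lowest myeloid) and the CD16⁺ > CD16⁻ orderings are stable test
surfaces — adjacent middle ranks differ by less than their donor SDs and
are reported, not asserted.

## The synthetic cohort

The generator emulates a 22-donor quantitation study:

* **Donor-level truth.** Each subset's true ABC is normal with the
  configured cohort mean/SD. The six anchored subsets use the reported
  healthy-donor cohort averages (memory B 634 692 ± 68 919; CD16ˡᵒ NK 135 418 ± 43 632;
  effector CD8 T 205 559 ± 51 904; CD16⁺ monocytes 481 083 ± 137 931;
  CD16⁺ mDC 434 011 ± 129 432; basophils 72 308 ± 30 230 ABC units); the
  remaining twelve are interpolations consistent with the qualitative
  expression hierarchy. Two deliberate modelling choices:
  * a shared donor factor (weight 0.9) correlates subsets within donors.
    The expression hierarchy is consistent across donors even though the
    per-subset SDs overlap heavily; independent draws cannot produce that
    pattern, a correlated donor effect does, and the marginals keep the
    configured mean/SD.
  * `cohort_match` (default on) affinely standardizes the 22 draws so the
    synthetic cohort's *sample* mean/SD equal the configured values
    exactly. The reported numbers are summary statistics of one actual
    cohort, not hyperparameters of a superpopulation; matching them makes
    the 5% recovery band a measure of pipeline error rather than of cohort
    resampling noise (whose SE alone reaches 9% of the mean for
    basophils). Standardized values are floored at 2% of the subset mean.
* **Event level.** Antigen density is log-normal about the donor value with
  within-donor CV 0.25, parameterized so the *median* equals the donor
  value (median-unbiased recovery); fluorescence adds multiplicative
  log-normal noise (CV 0.05), the standard model for cytometry intensities.
  Marker channels draw from fixed log-normal components (median 10
  negative, 1600 positive, 200 lo, 3200 hi; log10 SD 0.15) separated ≥10×
  (hi/lo ≥4×) so threshold placement is unambiguous; on hi/lo channels a
  plain "+" renders at the hi component so no channel has more than three
  modes. Naïve B cells (60% bright, 5× separation) and pDCs (75% bright,
  4×) are two-component CD52 mixtures. Beads: 4 populations, 2000 events
  each, CV 0.02. Frequencies are realistic PBMC fractions summing to 0.895
  (remainder debris, low-FSC, excluded by the scatter gate). Composition is
  either `fixed` (equal depth per subset — the quantitation design, ≥5000
  events/subset) or `multinomial` (frequency-driven — the CDC wells).
* **Seeding.** One master seed; per-donor and per-stage streams derive
  deterministically from it. Identical config + seed reproduces tables
  bit for bit.

## The cytolysis model

Antibody-arm per-event death probability:

    p = bg + (max − bg) · logistic(s · (ln ABC − ln θ)) · (1 − prot)

with threshold θ = 2.7×10⁵ ABC (midpoint of the 2.6–2.8×10⁵ range a
density-dependent mechanism implies), slope s = 9 in ln-ABC, max lysis
0.95, control/background death 0.16, and CIP protection 0.85 for monocytes
and mDCs, 0.5 for basophils. CIP blocking multiplies protection by
(1 − blocking efficiency), default efficiency 0.9. Dead cells split
50/50 into necrotic (Annexin-V and 7-AAD bright) and apoptotic (Annexin-V
bright only); the 7-AAD⁺Annexin⁻ quadrant counts as necrotic, since any
7-AAD-permeant cell is dead. A fraction 0.35 of necrotic cells
disintegrates and leaves the event stream — this is what makes surviving
subsets appear *enriched* at equal analysed depth, as observed in the
assay. These values were chosen so that, at the cohort-mean antigen
densities, total lysis lands in the observed 44–68% (antibody) versus
13–19% (control) windows, every B/T subset shows detectable depletion while
NK/pDC/basophil subsets do not, and releasing CIP protection raises
purified-monocyte lysis by roughly 30 percentage points without reaching
T-cell levels.

The CDC scenario fixes donor antigen densities at the cohort means
(`donor_sd_scale = 0`): the assay models the average donor, and the
reported depletion pattern is a cohort-level statement, not one about
±2 SD tail donors. Wells are multinomial at 40 000 events; duplicate wells
per arm per donor; all wells are pooled as replicates for the Welch test
(valid because the scenario makes donor wells exchangeable), after seeded
down-sampling of every well to the smallest gated depth with streams paired
across arms by replicate index (identical paired wells therefore show
exactly zero depletion). Depletion/enrichment flags use unadjusted
two-sided p-values at α = 0.05 plus the sign of the difference, matching
the assay's presentation; a Holm-adjusted column is emitted alongside. The
test choice (Welch on replicate wells) is this package's decision — the
original analysis marks significance without naming a test.

Viability percentages are quantized to multiples of 2⁻²⁰ of a percentage
point (~10⁻⁶, far below reportable precision) so that the partition
identities — %live + %apoptotic + %necrotic = 100 and
%lysis = %apoptotic + %necrotic — hold *exactly* in floating point.

## CIP comparisons

CIP expression is compared on per-donor median MFI (CIP conjugates are not
ABC-calibrated), one-sided in the myeloid-greater direction by default,
Welch statistic, 4 donors. Simulated CIP levels: lymphocytes 300 (all three
CIPs), basophils 900, monocytes 750 for CD46/CD55 with CD59 near
lymphocyte levels (330–400), mDCs 450–600 — reproducing the pattern that
basophil and monocyte comparisons reach p ≤ 0.02 while monocyte CD59 does
not. `detection_power` reports simulated power (4 donors resolve a 2× MFI
ratio at donor CV 0.2 with power > 0.8); it asserts nothing about data.

## File formats

FCS is written as 3.1, list mode, float64 (`$DATATYPE D`, so round trips
are bit-exact) and read for versions 2.0–3.1 with F/D/I data types,
little- or big-endian. Only channel names and declared metadata round-trip;
compensation and acquisition keywords are out of scope. The tabular
fallback is CSV with `%.17g` floats (lossless for float64) read with
round-trip float parsing. Labels and per-event generative truth live in a
`.labels.tsv` sidecar keyed by 0-based event index, never in the primary
channels. Intensities are stored and analysed on the linear scale; any
log/biexponential transform is presentation-only.

## What passing tests do and do not show

The generator produces well-separated log-normal populations with no
spillover, no compensation error, no doublets, no time drift and no
acquisition dropouts. Passing tests therefore demonstrate that the
*analysis logic* — calibration arithmetic, threshold placement, boolean
assignment, counting, statistics — is correct and unbiased under the
stated noise model, at the reported effect sizes. They do not show that
density-valley thresholds would place correctly on compensated real data
with spectral overlap, nor that the logistic lysis model is mechanistically
accurate; the CDC model is phenomenological, chosen to reproduce the
observed qualitative pattern. The two unidentified HLA-DR± populations
surviving real CDC (likely granulocyte contamination) are not modelled.

## Problem sizes

Default test and acceptance runs use 22 donors × 18 subsets × 5000 events
(~2M events) for quantitation and 16 wells × 40 000 events for CDC —
depths at which median sampling error (<0.5% per donor) is negligible
against the 5% recovery band, while a full run stays in the
seconds-to-a-minute range on one CPU.
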