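# cytoabc

Quantitative flow-cytometry analysis of CD52 antigen density on human PBMC
subsets, and of the complement-dependent cytolysis (CDC) it drives.

Anti-CD52 antibody therapy depletes immune cells in proportion to how many
CD52 molecules each cell carries, modulated by complement-inhibitory
proteins (CIPs: CD46, CD55, CD59). `cytoabc` implements the full desk side
of that analysis for immunologists and assay developers:

* **Bead calibration** — convert median fluorescence intensity (MFI) to
  absolute antigen density in antibody-binding-capacity (ABC) units via a
  least-squares line in log10–log10 space through 4 calibrated bead
  populations: `log10 ABC = a + b·log10 MFI`.
* **Boolean phenotypic gating** — assign events to 18 lymphoid and myeloid
  PBMC subsets (naïve/memory B, four CD4 and four CD8 T stages, two NK, two
  monocyte and two myeloid-DC subsets, pDCs, basophils) using reproducible
  density-valley thresholds instead of hand-drawn gates, including hi/lo
  discrimination on CD16/CD56 and a bimodal CD52 split on naïve B cells and
  pDCs.
* **Quantitation** — per-subset median MFI → ABC, aggregated across donors
  (mean ± SD), with expression-hierarchy summaries.
* **CDC outcome analysis** — Annexin-V × 7-AAD viability quadrants
  (necrotic = 7-AAD⁺, apoptotic = Annexin-V⁺7-AAD⁻), total lysis,
  counting-bead absolute concentrations
  (`cells/100 µl = cell events × assigned count / bead events`), and
  treated-vs-control per-subset depletion tests (Welch) after equal-depth
  down-sampling; purified-population assays with CIP blocking.
* **Synthetic data** — an event-level generator whose defaults emulate the
  reported 22-donor healthy cohort (per-subset ABC means/SDs, bimodal subsets,
  antigen-density-dependent lysis with a ~2.7×10⁵ ABC threshold, CIP
  protection of monocytes/mDCs), so the entire pipeline is testable without
  instrument data. Dead cells partially disintegrate, which reproduces the
  apparent enrichment of surviving subsets.

## Worked example

```python
import cytoabc as ca

study = ca.run_quantitation_study(seed=1, n_donors=22, events_per_subset=5000)
print(study.quant.summary[study.quant.summary.subset.isin(
    ["Memory-B", "CD16lo-NK", "Basophils"])].to_string(index=False))
```

```
   subset      mean_abc       sd_abc  n_donors
Basophils  72280.398769 30246.217514        22
CD16lo-NK 135591.948299 43827.661054        22
 Memory-B 634342.542874 67561.580364        22
```

Each row is the cohort mean ± SD of the pipeline-recovered CD52 density in
ABC units (antibody molecules bound per cell): memory B cells carry the
most CD52 of any lymphoid subset (~6.3×10⁵ molecules), the CD56ʰⁱCD16ˡᵒ NK
subset the least (~1.4×10⁵), and basophils the least of any subset
(~7.2×10⁴) — recovered within a fraction of a percent of the configured
generative truth, because calibration, gating and median conversion are
close to unbiased at this event depth.

The CDC side:

```python
result = ca.run_cdc_study(seed=1)           # 4 donors, duplicate wells
print(result.counts[["subset", "control_mean", "treated_mean", "flag"]])
```

flags every B- and T-cell subset as depleted while NK cells, pDCs and
basophils survive (and typically appear enriched among remaining events),
with monocytes and myeloid DCs protected by their high CIP expression.

A command-line interface mirrors the library:

```bash
cytoabc run-all --seed 1 --outdir out/        # full pipeline + reports
cytoabc simulate --n-donors 4 --outdir sim/   # write synthetic FCS files
cytoabc calibrate sim/beads.fcs               # fit the standard curve
```

## Layout

```
src/cytoabc/
  events.py     EventTable container (channels × events + metadata + labels)
  io.py         FCS 3.1 writer / FCS 2.0–3.1 reader, tabular fallback
  simulate.py   synthetic donors, beads, CDC outcomes, counting beads
  calibrate.py  MFI↔ABC standard curve
  gating.py     density-valley thresholds, boolean subset assignment
  quantify.py   per-subset ABC, donor aggregation, hierarchies
  cdc.py        viability, absolute counts, depletion statistics
  cip.py        complement-inhibitor comparisons
  panels.py     shipped subset definitions and study scenarios
  study.py      reference-experiment runners
  pipeline.py   end-to-end runner with manifest
  cli.py        `cytoabc` command
```

See `docs/methods.md` for the generative model, parameter choices and
limitations.
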