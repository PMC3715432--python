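# fishloc

Quantification of **chromatin compaction** and **nuclear radial position**
from dual-colour 3D DNA-FISH image stacks of tissue sections, plus a
ground-truthed synthetic cohort generator so the entire analysis is testable
without external data.

## What it measures

For each nucleus, two fosmid probes flanking a locus are detected in a
3-channel super-resolution stack (DAPI, probe A, probe B):

* **d² (µm²)** — the squared 3D Euclidean distance between the two probe
  centroids. In interphase nuclei E[d²] = c·g: the mean squared distance
  grows linearly with genomic separation g (kb), with slope c (µm²/kb) set
  by local compaction. At fixed g, larger d² ⇒ decompacted chromatin.
* **fractional radius f** — the shortest in-plane distance e from the
  position probe to the nuclear periphery, divided by the nuclear radius R
  (half the broadest distance across the nuclear cross-section): f = e/R,
  0 = periphery, 1 = centre. Because tissue nuclei are not spherical, f is
  measured in the single z-slice containing the probe; d is fully 3D.

Per-object detection is Otsu thresholding of the ROI subvolume followed by
connected components and intensity-weighted centroids; channels are first
co-registered with predetermined (y, x) shifts. Groups (tissue regions,
signalling conditions) are compared with two-sided Mann-Whitney U tests
(exact for small tie-free samples, normal approximation with tie/continuity
corrections otherwise); matched explant pairs use the paired Wilcoxon
signed-rank test. The synthetic generator renders SIM-like cohorts —
ellipsoidal nuclei, Gaussian-chain probe pairs with E[d²] = c·g, a
parameterised fractional-radius law, Gaussian detection noise — with full
ground truth, at the study's sampling design of ≥50 nuclei per region in
each of 3 embryos.

## Worked example

Simulate a two-region cohort — a compact, peripheral locus
("stem_zone", c = 0.0015 µm²/kb) against a two-fold decompacted, more
central one ("neural_tube", c = 0.0030), both with g = 65 kb — and run the
full pipeline on the rendered images:

```python
from fishloc import demo_config, run_pipeline

cfg = demo_config("out", seed=1, n_embryos=1, n_nuclei=25)
res = run_pipeline(cfg)
print(res.manifest["counts"])
print(res.report[["metric", "stratum", "statistic", "p_two_sided", "method"]])
m = res.measurements.groupby("region")[["d2_um2", "frac_radius"]].median()
print(m)
```

prints

```
{'rois_in': 50, 'measured': 50, 'rejected': 0}
        metric    stratum  statistic  p_two_sided         method
0       d2_um2     pooled      112.0     0.000104  normal_approx
1       d2_um2  embryo:e1      112.0     0.000104  normal_approx
2  frac_radius     pooled      138.0     0.000735  normal_approx
             d2_um2  frac_radius
region
neural_tube  0.1863       0.6052
stem_zone    0.0615       0.3159
```

All 50 ROIs yield measurements. The neural-tube-like region shows the
expected ~2–3× higher median d² (decompaction) and a fractional radius
shifted towards the nuclear centre; both Mann-Whitney contrasts are
significant even at 25 nuclei per embryo (the statistic is the folded
U = min(U, n1·n2 − U)). `out/` contains
`measurements.csv` (the per-nucleus table), `report.csv`/`report.json`,
`manifest.json` (counts reconcile: ROIs in = measured + rejected), and box
/ radial-distribution plots.

The same run from the shell, plus analysis of an on-disk cohort
(TIFF stacks + ROI CSV + fosmid BED):

```bash
fishloc simulate -c run.yaml            # simulate + analyse in one pass
fishloc analyse  -c run.yaml            # cohort_dir: <stacks + rois.csv + fosmids.bed>
fishloc compare  -c run.yaml --metric d2_um2 --groups stem_zone neural_tube
fishloc validate -c run.yaml            # input checks, non-zero exit on errors
```

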