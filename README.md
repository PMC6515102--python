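# qamskit

Quality evaluation of multi-constituent herbal chromatograms, built around
the *Gastrodia elata* (tianma) tuber panel: **quantitative analysis of
multi-components by single marker (QAMS)**, external-standard
quantification, HPLC-fingerprint similarity against a consensus reference,
method-validation statistics, and hierarchical clustering of peak-area
profiles.

## The problem

A pharmacopoeial assay of a herbal medicine should track several active
constituents, but reference standards exist cheaply for only a few of
them. QAMS quantifies a whole panel from **one** affordable standard (here
gastrodin) by pre-establishing a *relative correction factor* for every
other analyte *k* against the marker *s* from their calibration slopes:

```
f_k/s = a_k / a_s                      (dimensionless)
C_k   = A_k / (a_s · f_k/s) · F        (mg per g of dry material)
```

where `A_k` is the analyte's peak area, `a` are calibration slopes
(area per mg/mL) and `F` is the extraction factor (effective mL of extract
per g of sample). Algebraically `C_k = A_k / a_k · F`, i.e. the
single-marker route is the external-standard method without its intercept
term — so the two methods differ per cell by exactly `(b_k / a_k) · F`,
which is the quantity every agreement statistic in this package is probing.

The package covers the full published workflow for the seven-constituent
panel (gastrodin, *p*-hydroxybenzyl alcohol, parishin E, *p*-hydroxy
benzaldehyde, parishins B, C, A):

* `qamskit.io` — containers and CSV I/O; the published calibration,
  peak-area, content and provenance tables ship as checksummed fixtures;
* `qamskit.calibration` — OLS calibration curves, inversion with range
  flags, S/N-based LOD/LOQ;
* `qamskit.quant` — correction factors, ESM/QAMS quantification, content
  summaries;
* `qamskit.validation` — RSD, C.V., spike recovery, paired t-test,
  dual-method agreement reports;
* `qamskit.fingerprint` — peak detection/integration, multipoint
  retention-time correction (0.5-min window), median-reference
  construction, correlation/cosine similarity;
* `qamskit.chemometrics` — z-scoring, ward-linkage clustering, dendrogram
  cuts, heatmap export;
* `qamskit.simulate` — a seeded generator of full-length synthetic
  chromatograms (EMG peaks, lognormal between-batch dispersion, retention
  jitter, drift, noise, shared matrix background);
* `qamskit.pipeline` — one-call reproduction of the published tables and
  an end-to-end synthetic run.

## Worked example

```python
>>> from qamskit import quant, validation
>>> from qamskit.io import load_reference_calibration, load_reference_peak_areas
>>> calib = load_reference_calibration()
>>> rcf = quant.compute_rcf(calib, "gastrodin")
>>> round(rcf.factors["p-hydroxybenzyl alcohol"], 4)
2.109
>>> cv = validation.cv_per_analyte(load_reference_peak_areas())
>>> round(float(cv["gastrodin"]), 1)
49.7
```

The first number is the correction factor of *p*-hydroxybenzyl alcohol
(its calibration slope 39300 over the marker's 18634): one gastrodin
standard now quantifies that analyte too. The second is the between-batch
coefficient of variation of the marker's peak area across the 21 producing
areas — every constituent disperses by 32–97%, which is why single-analyte
assays rank these materials poorly.

Running the numbered drivers reproduces each stage and writes its tables
under `results/`:

```sh
python analysis/01_calibration_and_rcf.py      # correction factors vs published
python analysis/02_fingerprint_dispersion.py   # C.V. row of the 21x7 panel
python analysis/03_contents_and_agreement.py   # content means, ESM/QAMS agreement
python analysis/04_cluster_samples.py          # ward clustering + heatmap
python analysis/05_synthetic_pipeline.py       # detection/quantification recovery
```

`analysis/05_synthetic_pipeline.py` prints, for seed 0:

```
21 batches rendered and re-measured (seed 0)
  peak-area recovery: worst cell off by 1.18%
  ESM-QAMS gap vs injected intercept term: max deviation 2.20e-15 mg/g
  fingerprint similarity to median reference: min 0.9972
```

i.e. on chromatograms whose ground truth is known, peak detection and
integration recover every generated area within ~1%, the two
quantification routes differ by exactly the injected intercept term, and
all 21 batch fingerprints score above 0.95 against the median reference.

The same pipeline is scriptable from the shell (`qamskit repro`,
`qamskit simulate`, `qamskit quantify`, `qamskit validate`,
`qamskit fingerprint`, `qamskit cluster`); see `qamskit --help`.

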