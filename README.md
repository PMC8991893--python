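# ctlong — longitudinal circulating-tumour-DNA analysis

`ctlong` is a Python toolkit for tracking a patient's tumour through serial
blood draws. It is written for analysts working with deep targeted or exome
sequencing of cell-free DNA (cfDNA) alongside matched tumour and germline
samples — the setting of longitudinal pancreatic-cancer monitoring, where the
tumour-derived fraction of plasma DNA (ctDNA) is small, artifact rates rival
true signal, and the clinically interesting questions are about change over
time: which mutations persist, which clones respond to treatment, which
emerge afterwards.

The package covers the full path from per-sample variant tables to clonal
dynamics:

- **Filtering** (`ctlong.filtering`) — a ten-stage patient-specific cascade:
  plasma calling (>=3 alt reads, one per strand, or >=1 read rescued by >=3
  alt reads in matched tumour), dbSNP-without-COSMIC removal, exonic-function
  and base-quality (>=25) filters, germline exclusion (no alt reads at >=20x),
  benign-control (chronic pancreatitis plasma) exclusion, multi-allelic
  consistency across serial draws, blacklist regions, and a Fisher-exact
  strand-bias test; population-frequency hits are flagged, not dropped. Every
  stage reports its counts and drop reasons.
- **Kataegis** (`ctlong.kataegis`) — localized hypermutation: clusters of >=6
  SNVs grouped within 10^4 bp gaps with mean inter-mutational distance
  <= 1000 bp, plus a sliding-window binomial hypermutation score (flagged at
  score >= 5) and pyrimidine-referenced substitution spectra.
- **Signatures** (`ctlong.signatures`) — 96-channel trinucleotide spectra and
  forward-selection non-negative least-squares refitting of signature
  exposures, with genomic-instability labels (DSBR / MMR / POLN) mapped from
  the fitted weights.
- **Copy number** (`ctlong.copynumber`) — GC/mappability LOESS normalization
  of 1 Mb read-depth bins, 6-state Viterbi segmentation under the purity
  model `log2((t·c + 2(1−t))/2)`, and maximum-likelihood tumour fraction
  over a contamination grid with golden-section refinement.
- **Clonal inference** (`ctlong.clonal`) — absence-aware binomial-mixture
  clustering of variant trajectories across timepoints, and exhaustive
  sum-condition-constrained search for the clone tree, with per-timepoint
  clone prevalences, stem-clone identification and emergence/decline calls.
- **Tracking** (`ctlong.tracking`) — mean mutant-allele-fraction series,
  tumour–plasma concordance, mutation loads, fragment-size profiles,
  hypergeometric pathway enrichment and driver/actionability oncoprint
  tables.
- **Synthetic cohorts** (`ctlong.simdata`) — a first-class generator of
  serial-plasma patients with clone trees, binomial read counts, every
  artifact class the cascade removes, kataegis clusters, signature-driven
  spectra and 167 bp-mode fragment sizes, all with machine-readable truth
  tables.

Real controlled-access patient data is not required anywhere: the package
validates itself end to end on its own generator.

## Worked example

Simulate a three-patient cohort, run the whole pipeline, and read off one
patient's results:

```python
from ctlong.pipeline import run_pipeline

summary = run_pipeline("out/", seed=1)
pt = summary["patients"]["PT01"]
print(pt["filter"][0])            # {'stage': 'call', 'n_in': 910, 'n_out': 766, 'n_dropped': 144}
print(pt["kataegis_events"])      # 1
print(pt["tumour_fraction"])      # {'true': 0.25, 'estimated': 0.2496}
print(pt["clonal"]["k"])          # 6
print(pt["clonal"]["dynamics"])   # ['declining', 'declining', ..., 'declining']
```

On this seed the cascade calls 766 of 910 plasma rows and the later stages
remove every injected artifact, leaving 421 candidate rows; the injected
8-SNV T>G cluster is detected as one kataegis event; the plasma tumour
fraction is estimated at 0.2496 against a simulated truth of 0.25; and the
clonal module clusters the serial VAFs into six trajectories (the five
simulated clones plus the clonal kataegis cluster), finds a
sum-condition-feasible tree and labels each clone's post-treatment
behaviour — here every baseline clone drops by more than half between the
pre-surgery and post-surgery draws, so all are labelled declining, matching
the simulated fall in tumour fraction from 0.25 to 0.05. `out/` holds the
per-patient TSVs: filter reports, candidate tables, kataegis events,
signature exposures, copy-number segments, prevalence matrices, Newick clone
trees, MAF series and oncoprint-ready actionability tables, plus the
simulated inputs and truth tables under `out/sim/`.

The same steps are available as a CLI for working with on-disk tables:

```
ctlong simulate --seed 1 --out sim/
ctlong filter --manifest sim/manifest.tsv --variants sim/variants \
              --blacklist sim/blacklist.bed --out filtered/
ctlong kataegis --variants filtered/PT01_candidates.tsv --out events.tsv
ctlong clones --variants filtered/PT01_candidates.tsv \
              --manifest sim/manifest.tsv --out clones/
ctlong run --seed 1 --out out/          # everything at once
```

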