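# comaqeeg

Quantitative EEG analysis for assessing consciousness levels in deep coma.

Patients in deep coma (Glasgow Coma Scale, GCS, 3–8) cannot cooperate with the
behavioural scoring that the GCS is built on, and inter-rater reliability of
bedside scoring is known to be poor. `comaqeeg` implements a fully
reproducible signal-processing and machine-learning pipeline that relates
band-limited EEG power structure to GCS level, for researchers in clinical
neurophysiology who want an objective complement to behavioural scores — and
a synthetic-cohort generator so the whole pipeline can be developed, tested
and benchmarked without any patient data.

## The method

Four bipolar channels (F3-F4, C3-C4, T3-T4, P3-P4, 500 Hz) are recorded under
a 35-minute staged protocol (rest 5′ → nurse interaction 5′ → rest 10′ →
family interaction 5′ → rest 10′; the interactions carry auditory and tactile
stimuli). After 50 Hz notch and 30 Hz lowpass filtering, each recording is
expanded into up to 9 analysis segments (each 10′ rest contributes its first
five minutes F5, second five minutes S5, and total T10) and decomposed into
the canonical sub-bands δ (0.5–4 Hz), θ (4–8), α (8–13), β (13–30).

For every channel × band, ten descriptors are computed — the Parseval energy
of the band-filtered samples

&nbsp;&nbsp;&nbsp;&nbsp;*Ex = (1/N) Σₖ |S(k)|² = Σₙ s(n)²*

and, from the Welch PSD (Hamming frames, 50 % overlap) restricted to the
band: the peak power *Maxp* and its frequency *Maxf*, the areas under the PSD
before/after the peak *A1, A2*, the ratios *A1/(A1+A2)*, *A1/A2*,
*A2/(A1+A2)*, and the squared-power sums *TPower = Σ P_f²*,
*NPower = TPower/fs*. That yields 160 features per segment. Features are
screened with Kruskal–Wallis across the six GCS groups plus Dunn–Bonferroni
post-hoc pairs, class imbalance is corrected with SMOTE
(*x_new = x_i + (x_knn − x_i)·w*, K = 5), and four classifier families
(Random Forest, 1-NN, bagged trees, cubic SVM) are compared under stratified
20-fold and leave-one-patient-out cross-validation with one-vs-rest
sensitivity, specificity, precision, F-score, G-mean and AUC.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Audit a balancing plan's arithmetic under the floor rule
(`floor(n · percent / 100)` synthetic instances per class):

```python
>>> from comaqeeg.balancing import plan_arithmetic
>>> plan_arithmetic(
...     counts={3: 74, 4: 36, 5: 79, 6: 81, 7: 57, 8: 18},
...     percents={3: 8, 4: 120, 5: 0, 6: 0, 7: 40, 8: 340},
...     printed_after={3: 79, 4: 79, 5: 79, 6: 81, 7: 81, 8: 79},
... )
       before  percent  after_floor_rule  after_stated  consistent
class
3          74     8.00                79            79        True
4          36   120.00                79            79        True
5          79     0.00                79            79        True
6          81     0.00                81            81        True
7          57    40.00                79            81       False
8          18   340.00                79            79        True
total     345    38.55               476           478       False
```

Reading: classes of 74, 36 and 18 instances raised by 8 %, 120 % and 340 %
all land on exactly 79; the stated 57 → 81 at 40 % is flagged because
57 + ⌊22.8⌋ = 79, not 81; the stated plan grows 345 instances to 478, a
38.55 % increase.

Run a small synthetic cohort end to end from the shell:

```bash
comaqeeg synth --out cohort/ --seed 1        # EDF files + manifest.csv
comaqeeg extract --in cohort/ --out features.csv
comaqeeg stats --features features.csv --out stats.json
comaqeeg classify --features features.csv --out metrics.json --k 20
comaqeeg run-all --out runs/demo --seed 1    # everything, one run directory
```

The run directory contains the 160-column feature table, the significance
grid, per-group band-energy means ± SEM, the SMOTE audit, per-model metric
reports for unbalanced and balanced variants, and pooled ROC scores. With the
default well-separated synthetic profiles, cross-validated accuracies come
out near 1.0 — the synthetic cohort is a correctness benchmark for the
machinery, not a difficulty benchmark (see `docs/methods.md`).

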