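# stsmap

Muscle-synergy extraction and center-of-mass phase-space mapping for
sit-to-stand analysis.

## The scientific problem

During a sit-to-stand movement the central nervous system coordinates many
muscles through a small number of **muscle synergies**: fixed weighting
vectors `W` over muscles, recruited by time-varying activation coefficients
`H`, so that the EMG envelope matrix factorizes as `V ≈ W·H` with all factors
nonnegative. The number of synergies `N_syn` a person uses is a compact
index of motor-control complexity, and is widely used to characterize
impairment.

This package links that muscle-level description to the **kinematics of the
body center of mass (CoM)**. The CoM trajectory in the sagittal plane,
expressed relative to the center of the base of support (the midpoint
between the two malleoli), defines two position–velocity phase spaces:

* cartesian — `(x, y)` = (antero-posterior, vertical) and their velocities;
* polar — magnitude `√(x² + y²)` and angle-from-vertical `arctan(x / y)`,
  and their velocities.

Within one upward (sit-to-stand) phase the 2-D phase-space trajectory never
revisits a state, so a mapping from phase-space position to muscle activity
is invertible along the cycle. The package trains a **Gaussian naive Bayes
classifier** from 2-D phase-space coordinates to the index of the most
active synergy, in all 8 variable-pair spaces plus a 2-D PCA space, with the
posterior probability of each synergy as the (deliberately fuzzy) mapping
output. Subjects are grouped by their `N_syn` — selected objectively with an
information criterion over NNMF fits of orders 1–6 — and group differences
in phase-space parameters are tested with Kruskal–Wallis.

Because no raw study data of this kind is publicly deposited, the package
ships a first-class synthetic-cohort generator with fully known ground truth
(true `W`, `H`, `N_syn`, noiseless linkage kinematics), so every stage of
the pipeline is verifiable end to end.

Intended users: movement scientists and biomedical engineers analysing
multi-channel surface EMG plus marker kinematics of repeated sit-to-stand
cycles, and anyone needing a tested reference implementation of
NNMF-with-order-selection plus state-to-synergy mapping.

## Worked example

```python
import stsmap as sm

cohort = sm.generate_cohort(sm.CohortConfig(snr_db=20.0), seed=11)
result = sm.run_study(cohort, sm.StudyConfig(), seed=11)

print("group sizes:", {n: len(m) for n, m in result.groups.items()})
print("vy max Kruskal-Wallis:", result.stats["vy"]["max_mean"])
for n, res in sorted(result.mappings.items()):
    table = res.accuracy_table()
    best = max(table, key=table.get)
    print(f"N_syn={n}: best mapping = {best} ({table[best]:.3f}), "
          f"PCA 2D explains {res.pca_explained_fraction:.1%}")
```

prints

```
group sizes: {3: 7, 4: 5}
vy max Kruskal-Wallis: {'H': 8.0769, 'p': 0.0045, 'significant': True}
N_syn=3: best mapping = polar angle position-velocity (0.953), PCA 2D explains 97.2%
N_syn=4: best mapping = polar angle position-velocity (0.958), PCA 2D explains 97.8%
```

Reading the output: the 12 synthetic subjects were generated 7 with three
synergies and 5 with four, and order selection on the observed noisy
envelopes (20 dB SNR) recovered that split exactly. The 4-synergy group was
generated with higher vertical CoM velocity peaks, and the Kruskal–Wallis
test on the maximum vertical velocity flags that difference (p < 0.05).
Each accuracy is the held-out (stratified 20% test split) fraction of
phase-space samples whose most-active synergy is predicted correctly by the
fuzzy mapping in that 2-D space.

## Command line

Each stage is also exposed as a thin CLI over the library:

```bash
stsmap synth --config cohort.yaml --out data/cohort --seed 1
stsmap preprocess --cohort data/cohort --out out/pre
stsmap com        --cohort data/cohort --out out/com
stsmap synergy    --cohort data/cohort --out out/syn --seed 1
stsmap map        --cohort data/cohort --out out/map --seed 1
stsmap study      --cohort data/cohort --out out/study.json --seed 1
```

Cohorts are plain-text directory trees (per subject `emg.csv`,
`markers.csv`, `truth.json`, plus a cohort-level `config.yaml`).

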