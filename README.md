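# eegtopo

Topological persistence features and cycle-ratio node importance for
multichannel EEG functional connectivity.

## What it does

Resting-state EEG group differences (for example between first-episode
schizophrenia patients and healthy controls) can show up not in raw band
power but in the *shape* of the functional connectivity network.  This
package extracts that shape with persistent homology and turns it into
features a standard classifier can use:

1. **Band decomposition** — each recording is zero-phase band-pass
   filtered into the clinical bands delta (1–3 Hz), theta (4–7), alpha
   (8–12), beta (13–30) and gamma (31–49 Hz), and cut to an analysis
   window.
2. **Connectivity** — channels become nodes with dissimilarity
   `D_ij = 1 − |r_ij|`, `r` the Pearson correlation over the window.
3. **Vietoris–Rips persistence** — growing a threshold ε over `[0, max
   D_ij]`, components (H0) and 1-cycles (H1) appear and die; each class is
   a point `(birth, death, dim)` in a persistence diagram.  H0 deaths are
   exactly the minimum-spanning-tree edge weights; H1 comes from GF(2)
   boundary-matrix reduction of the flag complex.  A deliberately naive
   full-enumeration reducer is shipped alongside as an independent oracle.
4. **Vectorization** — each diagram is summarized per homology dimension
   by persistence landscapes λ_k(t), Betti curves β(ε), diagonally
   antisymmetrized Gaussian heat-kernel rasters, and persistence entropy
   `E = −Σ p_i log p_i`, `p_i = (d_i − b_i)/Σ(d_j − b_j)`.  Curves and
   rasters are reduced to 1- and 2-norm amplitudes, giving a frozen
   22-feature vector per (subject, band), plus the band index.
5. **Evaluation** — LR / SVM / random-forest / LightGBM classifiers under
   stratified subject-grouped cross-validation, univariate feature
   selection at an accuracy threshold, and nested grid-search tuning.
6. **Node importance** — the most persistent 1-cycles select thresholded
   subgraphs in which every node is scored by its *cycle ratio* (how often
   it sits on other nodes' shortest cycles); top-10 nodes are tallied
   across segments, bands and subjects to localize the channels that carry
   the topology.

Because clinical EEG of this kind is rarely shareable, the package also
ships a synthetic-data generator that plants group-specific correlation
rings (a controllable 1-cycle in channel-correlation space), so the entire
chain is testable end to end.

## Worked example

```python
from eegtopo import SimSpec, make_study, run_pipeline, PipelineConfig
from eegtopo.classify import crossval_eval

patient = SimSpec(n_subjects_per_group=10, n_channels=12, duration=60.0,
                  latent_cycles=[[0, 1, 2, 3, 4, 5]], seed=0)
control = SimSpec(n_subjects_per_group=10, n_channels=12, duration=60.0, seed=1)
cohort = make_study(patient, control)

config = PipelineConfig(window=(0.0, 60.0), seed=0)
table, report = run_pipeline(cohort, config)
print(f"{report['n_rows']} feature rows "
      f"({report['n_recordings']} subjects x {report['n_bands']} bands)")
print(table[["subject_id", "band_name", "label", "f2", "f10", "f22"]]
      .head(3).to_string(index=False))

result = crossval_eval(table, classifiers=("LR", "GBM"), k=5, seed=0)
for name, m in result.metrics.items():
    print(f"{name}: accuracy={m['accuracy']:.3f} precision={m['precision']:.3f} "
          f"recall={m['recall']:.3f} f1={m['f1']:.3f}")
```

prints

```
100 feature rows (20 subjects x 5 bands)
 subject_id band_name   label       f2      f10      f22
patient_005     delta patient 0.021972 0.363798 0.724154
patient_005     theta patient 0.014737 0.270691 0.681295
patient_005     alpha patient 0.013360 0.295336 0.832326
LR: accuracy=1.000 precision=1.000 recall=1.000 f1=1.000
GBM: accuracy=1.000 precision=1.000 recall=1.000 f1=1.000
```

`f2` is the H1 landscape amplitude (p = 1, one layer), `f10` the H1 Betti
amplitude (p = 1), `f22` the H1 persistence entropy; patients carry a
planted six-channel correlation ring, so their 1-cycle features are
systematically larger and the grouped five-fold CV separates the groups
perfectly at this effect size.

The same chain is available from the shell:

```bash
eegtopo simulate --out-dir cohort --seed 0 --subjects 10 --duration 60
eegtopo extract cohort/*.csv --out features.csv --window 0 60
eegtopo classify --features features.csv --report report.json
eegtopo cycles cohort/patient_*.csv --out-dir tallies --segment-length 20
```

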