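# braintensor

Group-level identification of brain networks — including their subcortical
extent — from multi-subject resting-state BOLD data, by temporal
synchronization and low-rank tensor decomposition, with ROI statistics and a
seed-based comparison. The package targets researchers who want to map how
strongly small subcortical nuclei (central lateral thalamus, ventral
tegmental area, basal ganglia, ...) participate in cortical networks such as
the default mode network (DMN), and ships a synthetic-data generator with
full ground truth so every stage can be validated end-to-end.

## The model

Subjects' row-normalized data matrices are temporally aligned by orthogonal
transforms (BrainSync-style: the orthogonal Procrustes solution per subject
against a jointly estimated *virtual reference subject*), stacked into a
tensor `X ∈ R^{V×T×S}`, and factorized as a canonical polyadic (CP) sum of
rank-1 networks

    X ≈ Σ_{r=1}^{R} λ_r · a_r ∘ b_r ∘ c_r,

with `a_r` the spatial map over grayordinates (cortical vertices +
subcortical voxels), `b_r` the temporal dynamics, `c_r` the subject
participation, and `λ_r` the network magnitude. The solver (NASCAR-style)
grows the rank one component at a time, warm-starting from the lower-rank
solution and re-optimizing all factors with Nadam updates. The network of
interest is selected by correlation with a cortical template; its
subcortical map is expressed relative to the 95% quantile of its cortical
map, upsampled trilinearly, and quantified per ROI with one-sided Welch
t-tests against each nucleus's containing region, corrected by
random-field-theory resel counts (volume/FWHM³). See `docs/methods.md` for
the full account.

## Worked example

```python
from braintensor import SynthConfig, generate_dataset, GroupNetworkModel

# default study conditions (V=2000 grayordinates, T=300, snr=2, temporal
# misalignment on), 16 subjects
cfg = SynthConfig(n_subjects=16, seed=9)
dataset, truth = generate_dataset(cfg)

model = GroupNetworkModel(dataset, rank=6)
results = model.fit(seed=9)
print(results.summary())

maps = results.network_maps(truth.dmn_cortical_template())
print(f"selected component: {maps.component_index} "
      f"(strength rank {maps.component_index + 1})")
table = results.roi_statistics(maps, truth.atlas,
                               [("CL", "thalamus"), ("VTA", "brainstem")])
print(table.table[["roi", "median", "t_statistic", "p_corrected"]].to_string(index=False))
```

Output (about a minute on one CPU):

```
Group network model (CP decomposition)
  subjects: 16   timepoints: 300   grayordinates: 2000
  rank: 6   explained variance: 0.5977
  synchronized: True (iterations: 20, converged: False)

 component  magnitude  var_fraction
         0   115.3486        0.4137
         1    48.2872        0.0737
         2    40.5711        0.0479
         3    32.2825        0.0325
         4    29.3945        0.0273
         5    10.4896       -0.0061

selected component: 1 (strength rank 2)
roi   median  t_statistic  p_corrected
 CL 0.828875    12.461394 2.055798e-23
VTA 0.865817     7.689040 3.652914e-10
```

Reading the numbers: the strongest component (index 0) is the global
"physiological" signal; the template-matching network is the *second*
strongest, as expected for the DMN. Its normalized subcortical map sits at
~0.83 of cortical strength inside the toy CL and ~0.87 inside the toy VTA,
both significantly above their containing regions after random-field-theory
correction — the planted sign structure, recovered end to end from
misaligned, noisy multi-subject data.

A thin CLI wraps the same functionality:

```bash
braintensor simulate --out sim/ --subjects 40 --seed 0
braintensor run --dataset sim/dataset.h5 --atlas sim/atlas.nii.gz \
    --atlas-labels sim/atlas_labels.json --template sim/template.tsv \
    --rank 8 --seed 0 --out out/
braintensor split-half --dataset sim/dataset.h5 --template sim/template.tsv
```

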