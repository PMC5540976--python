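# voxelgrain

Does fMRI orientation decoding in human V1 rest solely on coarse
*global areal maps* (radial and vertical response biases), or do
fine-grained, columnar-scale selectivity patterns contribute at
conventional 2-mm resolution?  The two accounts are hard to separate
because the **voxel gain field** — voxel-to-voxel differences in
sensitivity to neural activity — turns even a perfectly smooth coarse
effect into a high-spatial-frequency voxel pattern.  A gain is strictly
positive, though, so it can never invert the sign of a between-condition
contrast.  Voxels inside a small quarterfield patch that *reliably*
prefer the orientation opposite to the coarse bias are therefore the
signature of fine-grained information.

`voxelgrain` implements that logic as a tested, reusable pipeline for
simulated (or user-supplied) t-value patterns:

* **Simulator** — orientation-column sheets with controllable columnar
  amplitude, coarse radial/vertical biases, a strictly positive
  log-normal gain field and noise, realizing three worlds:
  `coarse_only`, `fine_only`, `mixed`.
* **GLM** — block-design matrices (one predictor per condition per
  subrun), gamma HRF, OLS t-patterns.
* **Preference labeling** — per-voxel radial/tangential (gratings) or
  vertical/horizontal (spirals) labels from training data only.
* **Decoding** — linear SVM (C = 1), four-fold leave-subrun-out
  cross-validation, voxel selections (all / majority / minority
  preference set), spatial-shift controls (1–6 mm).
* **Replicability** — the cosine-type index
  `⟨t_train, t_test⟩ / (‖t_train‖‖t_test‖)` (no mean-centering, so signs
  must replicate), participant bootstrap, ROI ANOVAs.

## Worked example

Simulate the default mixed world (18 subjects, gratings), decode with
all voxels and with each preference set alone, and test whether
preferences replicate:

```python
import voxelgrain as vg

dataset = vg.generate_dataset(vg.mixed_scenario(seed=1, n_subjects=18,
                                                kinds=("grating",)))
result = vg.train_test_decode(dataset, selections=("all", "prefA", "prefB"))
print(result.group_summary().to_string(index=False))

rep = vg.crossval_replicability(dataset)
print(rep.group_table(n_boot=10000, seed=1)
        .query("roi == 'combined'").to_string(index=False))
```

```
   kind selection  shift_mm  n_subjects  mean_accuracy  p_vs_chance
grating       all       0.0          18       0.868056     0.000141
grating     prefA       0.0          18       0.868056     0.000098
grating     prefB       0.0          18       0.635417     0.000886
   kind  set_label      roi  n_subjects  mean_index   ci_low  ci_high  p_one_sided
grating     radial combined          18    0.201405 0.170976 0.233519       0.0001
grating tangential combined          18    0.074282 0.047317 0.102360       0.0001
```

Reading: gratings are decodable from all voxels (87%) and — the decisive
observation — from the *tangential-preferring minority alone* (64%,
signed-rank p < 0.001 vs chance), and both preference sets replicate
from training to test data (indices 0.20 and 0.07, bootstrap p = 1e-4).
In the `coarse_only` control world the same analysis yields zero
sign-inverted contrasts without noise, and with noise the
minority set does **not** generalize (negative replicability,
at-or-below-chance decoding): opposite preferences that decode and
replicate only arise when fine-grained structure is really there.

The same pipeline is scriptable from the shell:

```bash
voxelgrain simulate --seed 1 --out out/sim
voxelgrain decode --seed 1 --selection all --selection prefB --shift-mm 0,2,6 --out out/dec
voxelgrain all --seed 1 --out out/full
```

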