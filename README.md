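# jointatlas

Fully automated segmentation of the left atrium (LA), its four pulmonary
veins (LSPV, LIPV, RSPV, RIPV) and the left atrial appendage (LAA) from 3D
bright-blood MR angiography, by **joint-atlas-optimization**: instead of
registering each of the N annotated atlas images to the target one by one,
the target is embedded among the atlases and a *single* groupwise
registration is solved over the ensemble of transforms
μ = (T₀, T₁, …, T_N), minimizing the intensity variance across the group

```
C(μ) = Σ_v (I(T₀(v)) − Ī(v))² + Σᵢ Σ_v (Aᵢ(Tᵢ(v)) − Ī(v))²,
Ī = (1/(N+1)) [ I∘T₀ + Σᵢ Aᵢ∘Tᵢ ]
```

with Ī the **mean-shape image** — an average in intensity and, through the
transforms, in shape.  Atlas labels are fused by majority voting on the
mean-shape grid and carried back to the target through the inverted target
transform; a 3D Chan–Vese level set refines the result.  The conventional
pairwise baseline (per-atlas mutual-information registration, direct
propagation, the same fusion and refinement) is included for comparison —
the failure mode it suffers on thin distal structures (the PVs) is exactly
what the joint formulation repairs: a single misregistered atlas dilutes the
vote where agreement is weakest.

Intended users: researchers in cardiac image analysis who want a
reproducible multi-atlas/groupwise-registration pipeline, or a controlled
synthetic benchmark for registration-strategy comparisons.  Everything runs
from NumPy/SciPy; no external registration toolkit is wrapped.

## Worked example

The package ships a phantom generator (`jointatlas.phantom`) producing
LA-like atlas sets with known ground truth: an ellipsoidal chamber, four
thin PV tubes, an appendage bump, bright-blood appearance, and smooth random
inter-subject warps.  Segment one synthetic target with both strategies and
compare:

```python
import numpy as np
from jointatlas import (PhantomSpec, make_atlas_set, RegistrationConfig,
                        segment_joint, segment_pairwise, evaluate)

spec = PhantomSpec(shape=(48, 48, 32), spacing=(2.5, 2.5, 4.54), seed=7)
target, atlases = make_atlas_set(spec, 10, n_outliers=2)  # 2 hard atlases
imgs = [a.image for a in atlases]
labs = [a.labels for a in atlases]
cfg = RegistrationConfig(seed=21, iterations_per_resolution=300,
                         affine_iterations_per_resolution=100)

for name, run in [("joint", segment_joint), ("pairwise", segment_pairwise)]:
    res = run(target.image, imgs, labs, cfg)
    rep = evaluate(res.atlas_segmentation, target.labels)
    pv = np.mean([rep.dice[k] for k in ("LSPV", "LIPV", "RSPV", "RIPV")])
    print(f"{name:8s} whole-LA Dice {rep.dice['whole_LA']:.3f}  "
          f"S2S {rep.s2s['whole_LA']:.2f} mm  PV Dice {pv:.3f}")
```

Output (atlas stage, before level-set refinement; ~4 min single-core):

```
joint    whole-LA Dice 0.986  S2S 0.13 mm  PV Dice 0.938
pairwise whole-LA Dice 0.816  S2S 2.26 mm  PV Dice 0.498
```

With two of ten atlases deliberately deformed far from the group, the
independent pairwise registrations fail on those two and the majority vote
is diluted — most visibly on the thin PVs — while the joint optimization
pulls every member toward the common mean shape and keeps the vote
coherent.  `res.labels` holds the refined segmentation, `res.mean_shape`
the mean-shape image, and `res.history` the per-iteration objective traces.

A command-line interface mirrors the library:

```
jointatlas simulate atlas_dir --n-atlases 10 --seed 0
jointatlas segment atlas_dir out_dir --mode joint
jointatlas evaluate out_dir/segmentation.mhd atlas_dir/target_labels.mhd
```

Volumes are read/written as MetaImage (`.mhd/.raw`) or NIfTI
(`.nii/.nii.gz`); transforms serialize to JSON.

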