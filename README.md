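# lobereg — fissure-aided atlas registration for pulmonary lobe segmentation

`lobereg` segments the five pulmonary lobes (right upper/middle/lower,
left upper/lower) of a thoracic CT scan by deformably registering an
annotated atlas to the scan and pulling the atlas lobe labels through the
estimated displacement field.  It is aimed at researchers who need
automatic lobe maps from volumetric CT — for regional quantification,
lesion localisation or treatment planning — and at method developers who
want a small, fully testable reference implementation of the approach.

The pulmonary fissures are the physical borders between lobes, but they
are faint, thin sheets: registering CT intensity alone matches the lung
*outline* well while leaving the fissures in the wrong place.  The core
idea here is to give the fissures their own voice in the loss.  Fissures
are first enhanced with the Hessian sheet-similarity model

    S = F_structure · F_sheet,
    F_structure = Θ(−λ₃) · exp(−(|λ₃| − α)⁶/β⁶),   α = 50, β = 35
    F_sheet     = exp(−λ₂⁶/γ⁶),                     γ = 25

(|λ₁| ≤ |λ₂| ≤ |λ₃| are the Hessian eigenvalues at scale σ; a bright
sheet has one large negative eigenvalue whose eigenvector is the sheet
normal), thresholded at S > 0.1 and grouped into orientation-coherent
connected components (neighbouring normals with |e₃·e₃′| ≥ 0.95).  A
convolutional encoder-decoder then predicts a dense displacement field φ
from the 4-channel stack (subject CT, subject fissures, atlas CT, atlas
fissures) by unsupervised minimisation of

    L = MSE(f_CT, m_CT∘φ) + MSE(f_f, m_f∘φ) + λ·Reg(φ)

— fissure similarity weighted equally with lung-intensity similarity,
plus a forward-difference smoothness penalty Reg(φ).  The atlas lobe
labels are warped through φ (nearest neighbour) and post-processed so the
result exactly partitions the subject's own lung segmentation: every lung
voxel gets the label of its nearest valid lobe, no holes, no out-of-lung
labels.  Quality is measured with the Dice coefficient
2|X∩GT|/(|X|+|GT|).

A synthetic thorax phantom (body + two ellipsoidal lungs + rippled
fissure sheets + optional vessel distractors + known smooth deformation
fields) makes every stage testable without clinical data; see
`docs/methods.md` for the model, calibrations and limitations.

## Worked example

Register a deformed 64³ phantom subject back to the phantom atlas and
score the transferred lobes against the known ground truth:

```python
from lobereg import (PhantomSpec, make_phantom_pair, segment_lobes,
                     RegNetConfig)
from lobereg.lobe_transfer import dice_per_lobe

pair = make_phantom_pair(PhantomSpec(seed=0), amplitude=3.0, scale=8.0,
                         field_seed=1)          # max 3-voxel deformation
cfg = RegNetConfig.pipeline_default((64, 64, 64), seed=0)
lobes, extras = segment_lobes(pair.subject.ct, pair.atlas, cfg)
print({k: round(v, 4) for k, v in dice_per_lobe(lobes, pair.subject.lobes).items()})
```

prints (about two minutes on one CPU):

```
{'RU': 0.9594, 'RM': 0.9441, 'RL': 0.9667, 'LU': 0.97, 'LL': 0.9673, 'overall': 0.9615}
```

i.e. every lobe of the deformed subject is recovered with Dice ≥ 0.94
against ground truth, and the final map has no holes (it exactly
partitions the subject's lung segmentation).  For comparison, simply
copying the atlas labels without registration scores 0.955 overall.  On a
deformation that moves the fissures while leaving the lung outline fixed,
removing the fissure term from the loss leaves the intensity-only
registration with almost nothing to optimise — it stays near the
identity, while the fissure-aided loss pulls the sheets into place
(`scripts/acceptance.py` reports this ablation).

The same pipeline is available from the shell:

```sh
lobereg phantom --out-dir work --size 64 --seed 0
lobereg segment --subject work/subject_ct.nii.gz --atlas-dir work \
        --out work/lobes.nii.gz --prealigned --seed 0
lobereg evaluate --pred work/lobes.nii.gz --truth work/subject_lobes.nii.gz
```

`lungseg`, `fissure` and `train` expose the individual stages; every
command writes a JSON manifest (parameters, seeds, input hashes) next to
its outputs.  All volumes are NIfTI (`.nii`/`.nii.gz`).

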