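# gmnet — subject-wise gray-matter morphometric networks

`gmnet` builds and analyzes individual gray-matter (GM) structural networks
of the kind used to study network-level reorganization in cerebral small
vessel disease (CSVD) and other conditions: each subject's brain is
parcellated into 90 cortical and subcortical regions, the voxel-wise GM
volume (GMV) distribution of every region is summarized as a normalized
25-bin histogram, and the edge between regions *i* and *j* is the histogram
intersection

&nbsp;&nbsp;&nbsp;&nbsp;s(i, j) = Σₖ min(hᵢ(k), hⱼ(k)) / Σₖ hᵢ(k),

a symmetric similarity in [0, 1]. The resulting 90×90 matrix is binarized
over a sparsity sweep (10%–60% in 2% steps), and at every level the package
computes the standard graph-theoretical measures — clustering coefficient
Cₚ, characteristic path length Lₚ, global and local efficiency
(E_glob, E_loc), small-world indices γ, λ, σ = γ/λ against degree-preserving
rewired null networks, and nodal betweenness centrality (BC) — each
summarized across the sweep by its area under the curve (AUC). On top of the
per-subject measures it provides hub detection (BC AUC ≥ mean + 1 SD),
covariate-adjusted three-group ANCOVA with LSD post hocs, and
brain–cognition correlations with FDR control.

The package is aimed at methods researchers who want a tested, reproducible
reference implementation of this pipeline. Because subject-level MRI is
rarely redistributable, `gmnet` ships a first-class synthetic-cohort
generator that reproduces the statistical structure the analysis assumes —
region-specific GMV distributions with latent-factor correlation (yielding
small-world thresholded networks), two patient groups and one control group,
covariates, cognitive scores, and configurable group effects — so the whole
pipeline is testable end to end without any download. An optional NIfTI
reader extracts per-region values from a real modulated GM volume plus an
integer atlas label volume on the same grid.

## Worked example

```python
import numpy as np
from gmnet import (CohortDesign, generate_cohort, build_similarity_matrix,
                   analyze_subject)

design = CohortDesign(group_sizes={"CSVD-c": 5, "CSVD-n": 5, "control": 5},
                      seed=1)
cohort = generate_cohort(design)

subject = cohort[0]
S = build_similarity_matrix(subject)          # 90x90, symmetric, diag 1
res = analyze_subject(S, n_nulls=20, seed=7)  # sweep + metrics + BC

for name in ("Eglob", "Eloc", "Lp", "Cp", "gamma", "sigma"):
    c = res["curves"][name]
    print(f"{name:6s} AUC = {c.auc:.4f}  (min {c.values.min():.3f}, "
          f"max {c.values.max():.3f})")
```

Output for this seed:

```
Eglob  AUC = 0.2731  (min 0.157, max 0.789)
Eloc   AUC = 0.4585  (min 0.896, max 0.937)
Lp     AUC = 1.0850  (min 1.465, max 3.228)
Cp     AUC = 0.4223  (min 0.805, max 0.874)
gamma  AUC = 1.0107  (min 1.139, max 5.286)
sigma  AUC = 0.7863  (min 1.089, max 4.941)
```

Eglob rises and Lp falls as the network densifies across the sweep; γ and σ
stay above 1 at every threshold — the small-world regime. The AUC values
summarize each curve over the sparsity range [0.10, 0.60] (so a constant
curve of height v has AUC 0.5·v).

The full pipeline — simulate, build networks, metrics, hubs, statistics —
runs from the command line:

```bash
gmnet all --seed 1 --out run/        # full default cohort (49/121/74)
gmnet simulate --seed 1 --out cohort.tsv
gmnet build-net --cohort cohort.tsv --out matrices/
gmnet build-net --gm-volume gm.nii.gz --atlas aal90.nii.gz --out subject.tsv
gmnet metrics --matrix matrices/ --out metrics/
gmnet hubs --bc-auc run/nodal_bc_auc.tsv --out hubs/
gmnet stats --global-auc run/global_auc.tsv --nodal-auc run/nodal_bc_auc.tsv \
            --cohort run/cohort.tsv --out stats/
```

Every stage writes plain UTF-8 TSV (plus a JSON run manifest with all seeds
and resolved settings), reruns are byte-identical, and each stage can be
re-executed from the stored intermediates of the previous one.

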