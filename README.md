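# crossvae

Conditional-VAE integration of single-cell RNA-seq datasets with
**substantial batch effects** — the cross-*system* setting (different
species, organoid vs. tissue, cells vs. nuclei) where ordinary batch
correction under-integrates and aggressive correction destroys biology.

The package provides, in pure scientific Python (NumPy/SciPy/scanpy
stack, no deep-learning framework dependency):

* a conditional VAE (`CrossSystemVAE`) with three latent priors —
  standard normal, **VampPrior** (mixture of the encoder's posteriors at
  trainable pseudoinput cells), and a latent-space **Gaussian mixture** —
  plus a **latent cycle-consistency** penalty (compare each cell with its
  own system-swapped counterfactual) and an **adversarial discriminator**
  ablation;
* the full integration-evaluation suite: graph **iLISI** for batch
  mixing, **NMI-fixed** and per-type **Jaccard** via majority-relabelled
  Leiden clusters for cell-type preservation, a per-(cell type, sample)
  **Moran's I post/pre ratio** for within-cell-type preservation,
  batch-ASW, pre-integration batch-strength testing, condition-mixing
  iLISI, and the 0.6/0.4-weighted overall score with best-setting and
  representative-run selection;
* a **synthetic cross-system generator** with known ground truth
  (negative-binomial counts; system, sample and type-by-system shifts;
  missing populations; condition effects; within-type gene-program
  gradients) so every mechanism is testable without external downloads;
* grid orchestration (`run_grid` / `report`) and a thin `crossvae` CLI
  (`simulate`, `train`, `evaluate`, `grid`, `report`).

The model family follows a statsmodels-like shape: build a model from
data, `fit()` it, and work with the returned results object.

## The model in brief

For expression `x` and one-hot batch covariates `c = [system, sample]`:

```
z ~ q(z|x,c) = N(mu_phi(x,c), diag sigma_phi^2(x,c))      (encoder)
xhat = g_theta(z, c)                                       (decoder)

L = ||x - xhat||^2/2                                       reconstruction
  + kl_weight * KL(q(z|x,c) || p(z))                       prior regularisation
  + cycle_weight * MSE*(z, z'_j),  z'_j = E(G(z, c_j), c_j) cycle consistency
  + kappa * (- CrossEntropy(D(z), system))                 adversarial (ablation)
```

where `p(z)` is either `N(0, I)`, the VampPrior
`sum_l softmax(w)_l q(z | xpi_l, c_l)`, or a trainable Gaussian mixture,
and `MSE*` standardises each latent set per dimension before comparing.
See `docs/methods.md` for every convention and default.

## Worked example

```python
import numpy as np
from crossvae import (preset, generate, preprocess, CrossSystemVAE,
                      TrainConfig, ilisi, leiden_majority_relabel, nmi_fixed)

# two systems, four shared cell types with within-type gene-program
# gradients, and strong type-specific system shifts
ds, truth = generate(preset("gradient_rich",
                            n_cells_total=1500, n_genes=400, seed=0))
ds = preprocess(ds, min_cells=5)         # gene filter, median-normalise, log1p

baseline = CrossSystemVAE(ds, n_hidden=128).fit(
    TrainConfig(n_epochs=250, seed=0))
combined = CrossSystemVAE(ds, n_hidden=128, prior="vamp",
                          cycle_weight=1.0).fit(TrainConfig(n_epochs=250, seed=0))

for name, res in [("cVAE", baseline), ("VAMP+CYC", combined)]:
    emb = res.get_latent()               # cells x 15 posterior means
    derived = leiden_majority_relabel(emb, ds.cell_type, seed=0)
    print(f"{name:9s} iLISI={ilisi(emb, ds.system, 90):.3f} "
          f"NMI={nmi_fixed(derived, ds.cell_type):.3f}")
```

Output from this exact script:

```
cVAE      iLISI=0.254 NMI=1.000
VAMP+CYC  iLISI=0.954 NMI=0.997
```

Both models preserve the cell-type structure (NMI ~1), but the baseline
cVAE leaves the two systems largely unmixed (iLISI 0.25 — neighbourhoods
are dominated by one system), while the VampPrior + cycle-consistency
model mixes them strongly (iLISI 0.95) at essentially unchanged NMI —
the trade-off the package exists to improve. `res.summary()` prints the
fitted configuration, loss components and active-dimension diagnostics;
`res.prior_component_assignment()` shows which prior component claims
each cell (components track cell types, not systems).

## Layout

| path | contents |
|---|---|
| `src/crossvae/data.py` | `ExpressionDataset`, H5AD/MTX IO, preprocessing |
| `src/crossvae/synthetic.py` | ground-truth generator and presets |
| `src/crossvae/model.py` | priors, losses, `CrossSystemVAE` / `VAEResults` |
| `src/crossvae/nn/` | minimal autodiff core and MLP building blocks |
| `src/crossvae/metrics.py` | iLISI, NMI-fixed, Jaccard, Moran's I ratio, ASW, ... |
| `src/crossvae/grid.py` | variant grids, crash-safe result tables, reports |
| `src/crossvae/cli.py` | `crossvae` command-line entry point |
| `docs/methods.md` | full model, metric and generator documentation |
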