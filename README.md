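# megpeb — MEG source reconstruction with fMRI spatial priors

`megpeb` implements a parametric empirical Bayes (PEB) pipeline for the
MEG inverse problem, aimed at researchers who want to test how fMRI
activation maps perform as *soft* spatial constraints on distributed
source reconstruction — and at anyone who needs a self-contained,
simulation-backed reference implementation of the covariance-component
approach.

## The model

Sensor data follow the linear forward model **B** = **L X** + **E**,
where **L** is the lead field of a single-sphere head model (Sarvas
closed form, point magnetometers) and **X** the unknown cortical source
amplitudes. Sources are zero-mean Gaussian with covariance

&nbsp;&nbsp;&nbsp;&nbsp;Γ = Σᵢ exp(λᵢ) Qᵢ,

a weighted sum of fixed covariance components: a library of smoothed
cortical patches (multiple sparse priors) and, optionally, rank-1
components **Q**ᵢ = qᵢqᵢᵀ built from fMRI statistical maps — each
suprathreshold cluster is binarised, projected onto the cortical mesh by
Voronoi assignment, and smoothed with the truncated mesh Green's
function G = exp(σA) ≈ Σ_{k≤8} σᵏ/k! Aᵏ. The hyperparameters λ (and a
sensor-noise weight) are estimated by restricted maximum likelihood,
ascending the variational free energy *F* — a lower bound on the log
model evidence, reused for Bayesian model comparison. The MAP source
estimate is the posterior mean **X̂** = Γ**L**ᵀ**C**⁻¹**B**. Because
invalid priors receive vanishing weight, fMRI constraints inform but
never dominate the solution.

The package also regenerates a complete simulation study: an evoked
10 Hz dipole at MNI (−38, 43, 5) mm and an induced, trial-varying dipole
at (−54, −13, 5) mm, 100 trials over t ∈ [0.55, 0.85] s at three noise
levels, inverted under four prior variants (no priors / all / valid only
/ invalid only) and scored by ROC/AUC, peak and centre-of-mass
localization error, and VOI-eigenvariate time-course RMSE in time and
frequency domains.

## Worked example

```python
import numpy as np
from megpeb import (ComponentSet, SimConfig, SourceInversion, SmoothingSpec,
                    SyntheticPriorSpec, build_leadfield, build_msp_library,
                    build_prior_set, generate_fixture_geometry,
                    make_synthetic_statmap, simulate_trials)

mesh, sensors, sphere = generate_fixture_geometry(n_vertices=2000, seed=0)
lead = build_leadfield(mesh, sensors, sphere)

trials = simulate_trials(SimConfig(n_trials=100, snr_db=10.0, seed=0), mesh, lead)

spec = SmoothingSpec(adjacency=mesh.adjacency, sigma=0.6)
patches = build_msp_library(mesh, n_patches=256, spec=spec, seed=0, bilateral=True)
statmap = make_synthetic_statmap(SyntheticPriorSpec())
fmri = build_prior_set(statmap, mesh, height_T=5.0, extent_k=10, spec=spec)

model = SourceInversion.from_trialset(
    trials, lead, ComponentSet.with_white_noise(patches + fmri, lead.n_channels),
    mode="evoked")
result = model.fit()
print(f"free energy F = {result.free_energy:.1f}, "
      f"{result.n_iterations} iterations, converged = {result.converged}")
top = result.summary().nlargest(3, "weight_share")[["component", "weight_share"]]
print(top.to_string(index=False))
```

Output from this exact script (fixture seed 0):

```
free energy F = 85525.8, 9 iterations, converged = True
     component  weight_share
fmri cluster 2      0.564892
bilateral v735      0.122483
fmri cluster 1      0.113067
```

The fit concentrates ~68% of the source variance on the two fMRI
clusters sitting at the true dipoles (cluster 2 at the evoked source,
cluster 1 at the induced one), with a bilateral cortical patch picking
up part of the evoked response; the remaining 250+ patches and the
invalid cluster are shrunk toward zero. `result.source_power_map()`
then gives the per-vertex activity used for ROC scoring, and
`result.trial_posteriors()` the per-trial source time courses.

The same pipeline is scriptable from the shell (`megpeb simulate`,
`build-priors`, `invert --variant valid`, `evaluate`, `report`,
`verify`), with a flat `key = value` config file and checksummed run
manifests.

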