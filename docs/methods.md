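# Methods

## Model

`megpeb` solves the MEG inverse problem in a two-level Gaussian
hierarchy. At the first level, sensor data **B** (channels × samples)
are **B** = **L X** + **E** with white sensor noise; at the second, the
source amplitudes **X** are zero-mean Gaussian with covariance
Γ = Σᵢ exp(λᵢ)**Q**ᵢ over a fixed component library. Marginalising **X**
gives the sensor-level model covariance

    C(λ) = Σⱼ exp(λⱼ) Qⱼ^(sensor) + L Γ Lᵀ,

and the hyperparameters are estimated by restricted maximum likelihood —
equivalently, ascent on the variational free energy

    F(λ) = Σₜ log N(bₜ; 0, C) + log N(λ; η, Σ_η) + ½ log|2π Σ_λ|,

where the second term is a Gaussian hyperprior on the log weights and
the last a Laplace correction for hyperparameter uncertainty (computed
from the Fisher information at the optimum). `F` is used both as the
fitting objective and for model comparison between prior sets. The MAP
source estimate is the posterior mean **X̂** = Γ**L**ᵀ**C**⁻¹**B**,
linear in the data, so averaged-data and per-trial estimates come from
one fitted operator.

Assumptions worth stating: sources are constrained to mesh vertices with
fixed (surface-normal) orientation; noise is white at the sensor level
(the sensor component is extensible to a measured covariance); and all
temporal structure enters only through second moments — the model is
stationary within the analysis window.

## Forward model

The lead field uses the closed-form field of a current dipole in a
homogeneous conducting sphere, projected onto point magnetometers with
radial pickup orientation. Two exact properties of this model anchor the
test suite: a radial dipole moment produces no external field, and a
dipole at the sphere centre is silent. The oracle for the closed form is
an independent route through the magnetic scalar potential,
B = −μ₀∇U with U = −(q×r₀)·r / (4πF), differentiated symbolically.
Gradiometer baselines and realistic (boundary-element) head models are
out of scope. Internally all physics is SI (metres, tesla); the
user-facing mesh/MNI API is millimetres, x right, y anterior, z
superior.

## fMRI priors

A statistical volume is thresholded (face-connected clusters, height
threshold `height_T`, extent `extent_k`); each cluster is binarised,
its suprathreshold voxels assigned to their nearest mesh vertices
(Voronoi projection; voxels farther than 20 mm from the mesh are
dropped), and the resulting indicator smoothed with the truncated
Green's function of the mesh adjacency, G = Σ_{k=0..8} σᵏ/k! Aᵏ with
σ = 0.6 by default — the Taylor series of exp(σA), which is how the
subscripted rendering of this operator is interpreted here. Each
smoothed indicator q becomes a rank-1 component q qᵀ, normalised to
unit vector norm so hyperparameters are comparable across clusters;
registration error between modalities is handled solely by this
smoothing. Priors are binary by construction; continuous weighting by
statistic value is a documented extension point, not implemented.

## Patch library (sparse priors)

The no-fMRI baseline uses a library of smoothed cortical patches among
which ReML selects sparsely. Patch centres are drawn by greedy
farthest-point sampling (deterministic given a seed). Each centre
contributes the unilateral patch and a bilateral component (patch plus
its x-mirrored homologue), following the usual sparse-prior construction
for bilateral responses. The simulation study uses 256 components (128
centres) on the 2000-vertex fixture shell, which preserves the
centre-to-vertex density of the reference configuration this library
emulates (512 patches on an ~8000-vertex template mesh); a denser
library makes the no-prior inversion unrealistically accurate because
the dictionary then contains a near-exact atom for every source.

## Hyperparameter optimisation

Two ascent directions are available on the same penalized objective,
both wrapped in a backtracking line search that guarantees a
non-decreasing free-energy trajectory (asserted to 1e-8 in every run):

* `solver="ard"` (default): the multiplicative fixed-point update
  Δλᵢ = log(tr(C⁻¹QᵢC⁻¹S̄) / tr(C⁻¹Qᵢ)). Its rich-get-richer dynamics
  resolve the selection among highly correlated components by topography
  alignment, which is what makes sparse solutions land on the
  best-matching atoms.
* `solver="fisher"`: a damped Newton step using the expected Fisher
  information, as in classical ReML schemes. It reaches the same optima
  on well-conditioned problems but, with an over-complete dictionary,
  can jump to arbitrary spanning subsets of correlated components.

Numerical choices: hyperpriors are N(−4, 16) on log λ after the data
second moment is scaled to unit mean eigenvalue and every sensor-space
component to unit mean diagonal (fitted weights are reported back on the
original scale); λ is clipped to ±32 in fit space (an exp-overflow guard
of ±500 applies when assembling covariances in physical units);
convergence is |ΔF| < 1e-4 or 128 iterations; steps are clipped to ±4
(ard) or max-norm 8 (fisher) per iteration, then halved up to 12 times
until F does not decrease. Degenerate inputs: B = 0 yields a zero
posterior and the closed-form log-normalizer; a non-PSD assembled
covariance (impossible under the exp parameterization unless a component
is corrupt) raises an error.

## Simulation conditions

The generator reproduces the study conditions: two fixed-orientation
dipoles at MNI (−38, 43, 5) and (−54, −13, 5) mm, moment 10 nA·m along
the vertex normal, t ∈ [0.55, 0.85] s at 600 Hz (181 samples; the
source content is band-limited well below Nyquist), 100 trials, white
sensor noise scaled per trial so total signal power over total noise
power matches the requested SNR (∞, 10 dB, −10 dB). Waveforms:
f₁(t) = sin(2π·10(t−t₀)+π/2) for the evoked source and
f₂(t; i) = sin(2π·24(t−t₀)/ρᵢ+π/2) for the induced one, with t₀ the
window start. The per-trial scale ρᵢ = i·δᵢ is drawn as ρᵢ ~ U(0.5, 2)
(frequencies 12–48 Hz on every trial); the literal per-trial law
δᵢ ~ U(lo, hi) is available but drives late trials toward DC. Note a
consequence of the +π/2 phase: every induced trial starts at amplitude
1, so the trial-averaged induced waveform keeps a coherent onset
transient and is temporally correlated with the evoked waveform — this
limits how cleanly the two sources separate in averaged second moments.

Synthetic fMRI volumes place Gaussian blobs (σ = radius/2, default
radius 10 mm, peak T = 10, 4 mm voxels) at both dipoles and one invalid
site ≥ 30 mm from either dipole; thresholding at T = 5 with extent 10
recovers one cluster per blob.

The fixture geometry is a corrugated spherical shell (base radius 70 mm,
seeded smooth radial waves, 2000 vertices by default) inside a 90 mm
head sphere, with a 275-channel radial-magnetometer helmet at 120 mm.
The shell is blended so one vertex sits exactly at each dipole, and a
deterministic local wave guarantees the normal there is never radial
(a radially oriented source would be magnetically silent).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: cortical folding (the shell's smooth
topographies are more mutually correlated than real sulcal patterns, so
source confusions are more likely here than on a real mesh); gradiometer
pickup; physiological artifacts; head movement; and any forward-model
mismatch between simulation and inversion (the same lead field generates
and inverts the data, an idealisation that makes the noiseless no-prior
inversion more accurate than it would be in practice).

## The simulation study and its evaluation

For each noise level the trial set is inverted under four prior
variants: the patch library alone ("none"), plus all fMRI components
("all"), the valid components only ("valid"), or the invalid component
only ("invalid"). Hyperparameters are fitted on the 100-trial average
(the evoked pipeline) — this is what gives the reconstruction its noise
robustness, since averaging suppresses sensor noise tenfold — and the
per-trial posteriors reuse the fitted operator. The induced fitting
path on trial-accumulated second moments (`mode="induced"`) is
available for analyses where non-phase-locked power must drive the fit.

Scoring conventions (each the package's fixed choice where several were
possible): ground-truth labels are all vertices within 10 mm of a true
dipole; the detection map is the per-vertex RMS posterior amplitude over
all trials and samples, normalised to max 1; ROC curves sweep 101
uniform thresholds on [0, 1] with (0,0)/(1,1) endpoints appended and
AUC by trapezoid (their stepped appearance at few positives is
expected); the mesh is partitioned by proximity to the true sources
before per-source scoring; the centre of mass is the amplitude-weighted
centroid of the connected suprathreshold cluster (50% of the regional
peak) containing the regional peak; VOI time courses are the first
eigenvariate (dominant singular mode scaled by its singular value, sign
matched to the VOI mean) over a 10 mm radius; time-domain RMSE
normalises both signals to unit maximum amplitude (simulated moments
carry arbitrary scale); frequency-domain RMSE compares single-sided
amplitude spectra of the unit-normalised signals. The RMSE battery is
reported at every noise level; the headline averaging-effect check uses
the 10 dB, no-priors cell. An LCMV "virtual sensor" filter (unit gain
at the target lead-field column, diagonal loading when the data
covariance is near-singular) is included as an experimental comparison
column only.

Problem sizes used throughout: 2000 vertices, 275 channels, 100 trials,
256 + up to 3 components, five-seed batteries; unit tests use a
300-vertex shell. One full battery (60 inversions plus evaluation) runs
in minutes on a single CPU.

## Reproducibility plumbing

A single global seed expands to per-stage seeds by a fixed counter
scheme (seed·1000 + stage offset + 10·noise-index, mod 2³¹), so any
stage can be rerun independently and reproducibly. The CLI writes a
run manifest with SHA-256 checksums and per-stage wall-clock times;
`megpeb verify` re-checks them. Identical configuration implies
identical metrics end to end (asserted in the test suite).

## Known limitations

* The quasi-spherical fixture makes distinct source locations produce
  similar sensor topographies; with an over-complete patch dictionary
  the ReML optimum is then nearly degenerate across component subsets,
  and on some seeds a valid fMRI cluster receives negligible weight in
  the *noiseless* averaged fit even though it is the best-aligned
  single component (the onset-coherent induced average compounds this
  by blending the two sources' second moments). The prior benefit is
  most stable at the noisy conditions, where it matters most.
* Free energies are comparable only across fits of the same data (the
  internal data rescaling is data-dependent).
* The eigenvariate sign convention (correlate with the VOI mean) can
  flip relative to the simulated truth on individual induced trials,
  inflating per-trial RMSE.
* Real-data workflows (NIfTI statistical volumes, GIfTI/CSV surfaces
  and sensor tables) are supported at the format level, but the
  package contains no coregistration; inputs are assumed to share the
  MNI-style frame.
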