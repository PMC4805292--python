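# pmfbind

Umbrella-sampling analysis for one-dimensional binding problems: reconstruct
a potential of mean force (PMF) from biased reaction-coordinate timeseries
with the weighted histogram analysis method (WHAM), quantify its statistical
error by bootstrap, and convert it into a standard dissociation constant for
a pore blocker sampled inside a cylindrical restraint.

## Who this is for

Molecular-modelling studies of ion-channel blockers (peptide toxins and
toxin-mimetic polymers on K⁺ channels such as Kv1.3) commonly estimate
affinity by pulling the ligand along the pore axis *z*, umbrella-sampling
overlapping harmonic windows, and integrating the resulting PMF. `pmfbind`
implements that entire post-processing chain as a tested desk-scale package,
plus an overdamped Langevin generator that produces umbrella-sampling-like
data from *known* ground-truth free-energy profiles — so every estimator in
the chain can be validated against exact answers.

## The model

With the ligand's centre of mass confined to a cylinder of radius *R*
during sampling, the association constant follows from the 1D PMF *W(z)*
(anchored to zero in bulk):

```
Kd⁻¹ = 1000 · π R² · N_A · ∫_{z_min}^{z_max} exp[−W(z)/kT] dz
```

with *z*min/*z*max bracketing the bound state and the bulk, and N_A
Avogadro's number.  *W(z)* is estimated by self-consistent WHAM from the
per-window histograms n_ij:

```
P_j = Σ_i n_ij / Σ_i N_i exp[(f_i − c_ij)/kT],   exp(−f_i/kT) = Σ_j P_j exp(−c_ij/kT)
```

where c_ij = ½k_s(z_j − z0_i)² is the bias of window *i* at bin centre *j*.
Saved samples are declared decorrelated when their autocorrelation has
fallen to 1/e; the PMF's random error is the maximum pointwise standard
deviation across 10 bootstrap pseudo-datasets (resampling with duplication
within each window); convergence is diagnosed by recomputing the profile
depth on growing fractions of the data.  Single-site fractional block
C/(C+Kd) links Kd to electrophysiology readouts.

## Worked example

A complete synthetic study from the shell — a 6 kT Gaussian binding well at
z = 2 Å, eight umbrella windows (k_s = 4 kT/Å², 1.5 Å apart), ~11k samples
per window saved every 3 ps:

```yaml
# study.yaml
simulate:
  truth: {kind: double_well, depth1: 6.0, center1: 2.0, depth2: 0.0,
          center2: 6.0, width: 1.2, barrier: 0.0, z_lo: -2.0, z_hi: 12.0}
  z_first: 0.0
  z_last: 10.5
  spacing: 1.5
  k_s: 4.0
  seed: 1
  dt: 0.005
  n_steps: 6667200     # 11112 saved samples/window at 3 ps
  s_save: 600
```

```sh
$ pmfbind simulate --config study.yaml --outdir sim
wrote 8 windows + metadata.txt to sim
$ pmfbind wham --metadata sim/metadata.txt --bin-width 0.25 \
      --z-lo -0.5 --z-hi 11.25 --out pmf.dat
wrote PMF (47 bins) to pmf.dat
$ pmfbind bootstrap --metadata sim/metadata.txt --bin-width 0.25 \
      --z-lo -0.5 --z-hi 11.25 --n-boot 10 --seed 2 --out pmf_sigma.dat
sigma_max = 0.1729 kT  (n_boot=10, decorrelation stride 2)
$ pmfbind kd --pmf pmf.dat --radius 8 --z-min 0.5 --z-max 10.0 --sigma-max 0.1729
integral_A = 541.1
Ka_per_M = 65.5177
Kd_M = 0.0152631
Kd_uM = 15263.1
Kd_uM_low = 12839.6
Kd_uM_high = 18143.9
```

Reading the numbers: the reconstructed profile carries a ±0.17 kT bootstrap
uncertainty; the Boltzmann integral of the well over the 8 Å-radius
cylinder gives Kd ≈ 15 mM, with the ±σ_max shift bounding it between 12.8
and 18.1 mM.  (A 6 kT well is deliberately weak — deep wells grow Kd⁻¹
exponentially, e.g. ~e¹⁰ tighter at 16 kT.)  Against the exact truth
profile the same integral gives 15.4 mM, inside the bootstrap band.

The same pipeline runs on external data: any two-column (time, z)
timeseries plus a metadata file declaring centres, spring constants and
their unit dialect (`kT`/`kcal/mol`, `half-k`/`full-k`) — see
`pmfbind.io`.

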