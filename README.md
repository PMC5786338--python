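# riboflux

Simulation and inference of mRNA translation dynamics from ribosome
profiling, for researchers studying translation elongation in yeast and
other organisms.

Ribosome profiling gives per-codon footprint counts, but counts conflate
the *unobstructed* elongation rate of a codon with time ribosomes spend
queued behind their neighbours, and standard ~30-nt libraries can miss
closely stacked ribosomes entirely. `riboflux` models translation as an
extended totally asymmetric simple exclusion process (TASEP) and uses
simulation-based inference to disentangle these effects.

## The model

A transcript of L codons carries ribosomes represented by their A-site
position. Initiation places an A-site on codon 2 at exponential rate α,
allowed only while the first 2+ℓ codons are clear (footprint ℓ = 10
codons). A ribosome at position *i* < L hops to *i*+1 at rate λ_i,
conditioned on the next ribosome being more than ℓ codons downstream;
at the stop codon it unbinds at rate λ_L, producing a protein (flux J =
terminations per unit time). Ribosomes whose A-sites are within 12
codons of a neighbour are "closely stacked" and may be undetected by the
profiling protocol (detection probability 1, 0.5 or 0 per scenario).

Inference per gene (footprint profile p(i) plus a TE-derived detected
density):

1. naive rates λ_i ∝ 1/p(i) — exact without interference;
2. a monotone search for the α whose simulated detected density matches
   the TE target (TE = c·ρ_detected, with c fitted on low-density genes);
3. iterative *error-site* correction: where simulated and experimental
   profiles disagree beyond a threshold, α and the local λ's are jointly
   re-optimized, then error sites are re-detected downstream;
4. global rescaling of (α, λ) so the simulated mean observed speed over
   codons [150, L] equals the experimentally measured 5.6 codons/s
   (profiles are invariant under this scaling).

Downstream analyses: observed vs unobstructed rate metagenes and their
interference gap, codon-group frequency curves, the Eq.-style linear
model y_i = Σ_k β_k x_{i,k} + ε of mean rate deviations on windowed
nascent-chain features (charge counts, Kyte–Doolittle hydropathy, PARS
scores) with exhaustive window scanning, exit-tunnel entropic
(S(x) = ln πr(x)²) and Coulomb potentials, and ribosomal drop-off
estimation from binned exponential density decay (A·e^(−QX),
r = 1 − e^(−Q/25)).

## Worked example

```python
import numpy as np
from riboflux.detection import SCENARIOS
from riboflux.inference import InferenceConfig, infer_gene, mean_observed_speed
from riboflux.io import TEScaling
from riboflux.synth import SynthSpec, generate_gene_set, generate_profiles
from riboflux.tasep import SimConfig, simulate

genes = generate_gene_set(SynthSpec(n_genes=1, length=300, seed=11))
profiles, te = generate_profiles(genes, SCENARIOS["none"], SimConfig(seed=5))
truth = genes[0].model

model, diag = infer_gene(
    profiles[truth.gene_id], float(te["te"].iloc[0]),
    TEScaling(c=0.83, n_used=1, residual_sd=0.0),
    SCENARIOS["none"], InferenceConfig(sim=SimConfig(seed=1)),
    gene_id=truth.gene_id,
)
print(f"alpha: true {truth.alpha:.4f}  inferred {model.alpha:.4f}")
print(f"lambda correlation: "
      f"{np.corrcoef(model.lambdas[1:], truth.lambdas[1:])[0, 1]:.3f}")
check = simulate(model, SimConfig(seed=99, n_samples=30_000))
print(f"calibrated speed over [150, 300]: "
      f"{mean_observed_speed(check, 150):.2f} codons/s")
```

prints

```
alpha: true 0.0506  inferred 0.0523
lambda correlation: 0.973
calibrated speed over [150, 300]: 5.62 codons/s
```

i.e. the initiation rate is recovered within ~3%, the per-codon
elongation-rate profile to r ≈ 0.97, and an independent re-simulation of
the normalized model reproduces the 5.6 codons/s calibration speed.

The same workflows are available from the shell via the `riboflux`
command (`synthgen`, `infer`, `simulate`, `metagene`, `features`,
`tunnel`, `dropoff`), each writing a JSON manifest that makes its
outputs reproducible from the recorded seed.

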