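"""Synthetic gene sets with the statistical structure the pipeline assumes.

The generator draws coding sequences from codon-usage weights, assigns
each sense codon a base elongation rate, layers optional positional
(ramp) multipliers and planted nascent-peptide feature effects on top,
draws gene-specific initiation rates, and produces sampled footprint
profiles plus TE values through the simulator, so every downstream
module can be exercised end to end with known ground truth.

Default regime: 300-codon genes; codon base rates spanning roughly 4-14
codons/s with usage biased toward fast codons; initiation rates
log-normal with median 0.1 /s (median time between initiations 10 s),
so transcripts carry on the order of one ribosome per 100 codons and
interference is present but light; termination at the stop codon is
slow (3 codons/s), producing the queueing signature upstream of the
stop.  TE values are the simulated detected density (per 100 codons)
times a calibration constant of 0.83.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .detection import DetectionScenario, densities, sample_profile
from .features import FeatureSpec, gene_feature_track
from .inference import InferenceConfig, mean_observed_speed
from .tasep import GeneModel, SimConfig, simulate

__all__ = [
    "SENSE_CODONS",
    "STOP_CODONS",
    "codon_base_rates",
    "codon_usage_weights",
    "SynthSpec",
    "SyntheticGene",
    "generate_gene_set",
    "generate_profiles",
]

_BASES = "TCAG"
STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    c
    for c in (a + b + d for a in _BASES for b in _BASES for d in _BASES)
    if c not in STOP_CODONS
)

# Mean-elongation-rate bins and their codon counts / usage levels: codon
# usage rises with speed (fast codons are used more often).
_MER_GROUPS = (
    # (n_codons, rate_lo, rate_hi, relative usage weight)
    (4, 4.0, 6.0, 0.25),
    (13, 6.0, 8.0, 0.9),
    (13, 8.0, 10.0, 1.6),
    (16, 10.0, 12.0, 1.9),
    (15, 12.0, 14.0, 2.25),
)


def _grouped_codons():
    """Deterministic assignment of the 61 sense codons to rate groups."""
    order = list(SENSE_CODONS)
    np.random.default_rng(20180116).shuffle(order)
    out = []
    k = 0
    for n, lo, hi, w in _MER_GROUPS:
        for j in range(n):
            rate = lo + (hi - lo) * (j + 0.5) / n
            out.append((order[k], rate, w))
            k += 1
    return out


def codon_base_rates() -> dict[str, float]:
    """Codon-specific base elongation rates (codons/s), spanning ~4-14."""
    return {c: r for c, r, _ in _grouped_codons()}


def codon_usage_weights() -> dict[str, float]:
    """Relative usage weights; faster codons are more frequent."""
    w = {c: u for c, _, u in _grouped_codons()}
    total = sum(w.values())
    return {c: u / total for c, u in w.items()}


@dataclass(frozen=True)
class SynthSpec:
    n_genes: int = 20
    length: int = 300                      # codons, stop included
    alpha_median: float = 0.1              # /s; median initiation interval 10 s
    alpha_sigma: float = 0.4               # log-normal sd of log alpha
    termination_rate: float = 3.0          # codons/s at the stop codon
    ramp: np.ndarray | None = None         # positional multiplier on rates
    planted_effects: tuple[tuple[FeatureSpec, float], ...] = ()
    rate_noise_sigma: float = 0.3          # log-normal site-to-site jitter
    pars_smooth: int = 5                   # PARS score AR smoothing window
    reads_per_codon: float = 300.0         # footprint depth of a well-covered gene
    dropoff_rate: float = 0.0
    te_constant: float = 0.83              # TE = c * detected density per 100
    calibrate_speed: bool = True           # pin true mean speed on [150, L]
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.length < 3:
            raise ValueError("need at least one gene of >= 3 codons")
        if self.alpha_median <= 0 or self.termination_rate <= 0:
            raise ValueError("rates must be positive")


@dataclass
class SyntheticGene:
    model: GeneModel                 # ground-truth rates, codons/s
    protein: str                     # one residue per codon (stop = '*')
    pars: np.ndarray                 # per-codon PARS-like structure score


def _draw_sequence(length, usage, rng) -> tuple[str, ...]:
    codons = list(usage)
    p = np.array([usage[c] for c in codons])
    body = rng.choice(len(codons), size=length - 2, p=p)
    seq = ["ATG"] + [codons[i] for i in body] + ["TAA"]
    return tuple(seq)


def _pars_track(length, smooth, rng) -> np.ndarray:
    raw = rng.normal(0.0, 1.0, length + smooth)
    kernel = np.ones(smooth) / smooth
    return np.convolve(raw, kernel, mode="valid")[:length]


def generate_gene_set(spec: SynthSpec) -> list[SyntheticGene]:
    """Draw gene models with known rates (deterministic given the seed).

    Per gene: codons from usage weights; lambda_i = base rate of the
    codon at i, times the ramp multiplier, times exp of the planted
    feature effects evaluated on the generated protein/PARS tracks,
    times optional log-normal jitter; alpha log-normal.  With
    ``calibrate_speed`` each gene's rates are jointly rescaled so its
    simulated mean observed speed over [150, L] is 5.6 codons/s, putting
    the ground truth on the experimentally calibrated scale.
    """
    rng = np.random.default_rng(spec.seed)
    base = codon_base_rates()
    usage = codon_usage_weights()
    genes = []
    for g in range(spec.n_genes):
        codons = _draw_sequence(spec.length, usage, rng)
        protein = str(Seq("".join(codons)).translate())
        pars = _pars_track(spec.length, spec.pars_smooth, rng)

        lam = np.array(
            [base.get(c, spec.termination_rate) for c in codons]
        )
        lam[0] = base.get("ATG", 8.0)
        lam[-1] = spec.termination_rate
        if spec.ramp is not None:
            ramp = np.asarray(spec.ramp, dtype=float)
            if ramp.size < spec.length:
                ramp = np.concatenate(
                    [ramp, np.full(spec.length - ramp.size, ramp[-1])]
                )
            lam *= ramp[: spec.length]
        for fspec, beta in spec.planted_effects:
            gene_input = pars if fspec.kind == "pars" else protein
            track = gene_feature_track(gene_input, fspec)
            track = np.nan_to_num(track, nan=0.0)
            lam *= np.exp(beta * track)
        if spec.rate_noise_sigma > 0:
            lam *= rng.lognormal(0.0, spec.rate_noise_sigma, spec.length)

        alpha = float(
            rng.lognormal(np.log(spec.alpha_median), spec.alpha_sigma)
        )
        model = GeneModel(f"synth{g:04d}", codons, alpha=alpha, lambdas=lam)
        genes.append(SyntheticGene(model=model, protein=protein, pars=pars))

    if spec.calibrate_speed and spec.length > 150:
        cfg = InferenceConfig()
        for g, gene in enumerate(genes):
            summary = simulate(
                gene.model, SimConfig(seed=int(spec.seed + 7919 * (g + 1)))
            )
            speed = mean_observed_speed(summary, cfg.speed_region_start)
            gene.model = gene.model.scaled(cfg.target_speed / speed)
    return genes


def generate_profiles(
    genes: list[SyntheticGene],
    scenario: DetectionScenario,
    sim_config: SimConfig | None = None,
    te_constant: float = 0.83,
    dropoff_rate: float = 0.0,
    reads_per_codon: float | None = None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Sampled detected footprint profiles and a TE table for a gene set.

    Each gene is simulated with a seed offset from ``sim_config.seed``;
    the detected profile is sampled one footprint per snapshot and the
    TE is the detected density (per 100 codons) times ``te_constant``.
    ``reads_per_codon`` sets the footprint depth (total footprints =
    depth x gene length); the default emulates a well-covered gene at
    300 reads per codon.  Returns ``(profiles, te_table)`` where the TE
    table also carries the true total density, enabling calibration
    closure tests.
    """
    if sim_config is None:
        sim_config = SimConfig()
    if reads_per_codon is None:
        reads_per_codon = 300.0
    profiles: dict[str, np.ndarray] = {}
    rows = []
    for g, gene in enumerate(genes):
        n_footprints = int(round(reads_per_codon * gene.model.length))
        # thin by roughly one lattice-turnover time so the sampled
        # footprints are effectively multinomial (independent) draws
        interval = max(sim_config.sample_interval, gene.model.length)
        cfg = SimConfig(
            burn_in_steps=sim_config.burn_in_steps,
            n_samples=n_footprints,
            sample_interval=interval,
            seed=int(sim_config.seed + 104729 * (g + 1)),
            detect_prob=scenario.detect_prob,
            stack_threshold=scenario.stack_threshold,
            dropoff_rate=dropoff_rate,
        )
        summary = simulate(gene.model, cfg)
        rng = np.random.default_rng(cfg.seed + 1)
        detected, _total = sample_profile(
            summary, scenario, rng, n_samples=cfg.n_samples
        )
        profiles[gene.model.gene_id] = detected
        dens = densities(summary, scenario)
        rows.append(
            {
                "gene_id": gene.model.gene_id,
                "te": te_constant * dens["rho_detected_per100"],
                "density": dens["rho_total_per100"],
                "rho_detected_per100": dens["rho_detected_per100"],
            }
        )
    return profiles, pd.DataFrame(rows)
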