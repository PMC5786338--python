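"""Extended TASEP model of mRNA translation.

A transcript is a 1-based lattice of L codons; position 1 is the start
codon and position L the stop codon.  A ribosome is represented solely
by its A-site position.  Initiation places a new A-site on codon 2 at
exponential rate ``alpha``, allowed only while the 5'-most A-site is at
least ``2 + footprint`` (the incoming footprint would otherwise overlap).
A ribosome with A-site at ``i < L`` hops to ``i + 1`` at rate
``lambda_i``, conditioned on the next A-site downstream being more than
``footprint`` codons away; at ``i == L`` it unbinds at rate ``lambda_L``
and a protein is produced.  With a nonzero drop-off probability each
completed hop may instead end in premature unbinding.

Two solvers are provided: a stochastic next-reaction simulation
(:func:`simulate`) and an exact stationary solution of the configuration
master equation (:func:`exact_steady_state`) for small systems, used as
an independent oracle.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve

from ._kernel import run_tasep

__all__ = [
    "GeneModel",
    "SimConfig",
    "SimulationSummary",
    "simulate",
    "exact_steady_state",
    "observed_rates",
    "write_gene_model",
    "read_gene_model",
    "write_snapshots",
]

DEFAULT_FOOTPRINT = 10  # codons; a 30-nt protected fragment
DEFAULT_ASITE_OFFSET = 6  # A-site codon within the footprint (covers i-5..i+4)


@dataclass(frozen=True)
class GeneModel:
    """A transcript with its initiation and per-codon elongation rates.

    ``lambdas[i - 1]`` is the rate at 1-based codon position ``i``; the
    last entry is the termination (unbinding) rate at the stop codon.
    """

    gene_id: str
    codons: tuple[str, ...]
    alpha: float
    lambdas: np.ndarray
    footprint: int = DEFAULT_FOOTPRINT
    asite_offset: int | None = None

    def __post_init__(self):
        if self.asite_offset is None:
            object.__setattr__(
                self,
                "asite_offset",
                min(DEFAULT_ASITE_OFFSET, self.footprint),
            )
        lambdas = np.asarray(self.lambdas, dtype=float)
        object.__setattr__(self, "lambdas", lambdas)
        object.__setattr__(self, "codons", tuple(self.codons))
        if len(self.codons) != lambdas.shape[0]:
            raise ValueError(
                f"{len(self.codons)} codons but {lambdas.shape[0]} rates"
            )
        if not self.alpha > 0:
            raise ValueError("initiation rate must be positive")
        if not np.all(lambdas > 0):
            raise ValueError("all elongation rates must be positive")
        if self.footprint < 1:
            raise ValueError("footprint must be >= 1 codon")
        if not 1 <= self.asite_offset <= self.footprint:
            raise ValueError("A-site offset must lie within the footprint")

    @property
    def length(self) -> int:
        return len(self.codons)

    def scaled(self, k: float) -> "GeneModel":
        """Multiply alpha and every lambda by ``k`` (profile-invariant)."""
        return replace(self, alpha=self.alpha * k, lambdas=self.lambdas * k)


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    Defaults follow the standard protocol of ~1e4 burn-in reaction events
    and ~3e4 recorded ribosome positions.
    """

    burn_in_steps: int = 10_000
    n_samples: int = 30_000
    sample_interval: int = 50
    seed: int = 0
    detect_prob: float = 0.0
    stack_threshold: int = 12
    dropoff_rate: float = 0.0

    def __post_init__(self):
        if self.burn_in_steps < 0 or self.n_samples < 0:
            raise ValueError("counts must be non-negative")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if not 0.0 <= self.detect_prob <= 1.0:
            raise ValueError("detect_prob must be in [0, 1]")
        if not 0.0 <= self.dropoff_rate < 1.0:
            raise ValueError("dropoff_rate must be in [0, 1)")


@dataclass
class SimulationSummary:
    """Steady-state summaries of one simulation run.

    Positions are 1-based; index 0 of per-position arrays corresponds to
    codon 1 (never occupied by an A-site, which enters at codon 2).
    Missing values (positions never visited) are NaN, not zero.
    """

    gene_id: str
    length: int
    rho_total: float                 # mean ribosomes per codon
    rho_detected: float              # same, counting detected ribosomes only
    site_occupancy: np.ndarray       # P(A-site at i), per position
    dwell_time: np.ndarray           # mean seconds an A-site spends at i
    observed_rate: np.ndarray        # 1 / dwell_time
    unobstructed_rate: np.ndarray    # copy of the model lambdas
    flux: float                      # proteins / s
    interference_prob: np.ndarray    # P(trailing A-site at i - footprint | A-site at i)
    snapshots: np.ndarray            # (n_snap, max_ribs) padded with 0
    snapshot_counts: np.ndarray      # ribosomes per snapshot
    n_terminations: int
    n_initiations: int
    n_dropoffs: int
    elapsed_time: float

    @property
    def rho_total_per100(self) -> float:
        return 100.0 * self.rho_total

    @property
    def rho_detected_per100(self) -> float:
        return 100.0 * self.rho_detected


def _max_ribs(length: int, footprint: int) -> int:
    return length // footprint + 2


def simulate(model: GeneModel, config: SimConfig) -> SimulationSummary:
    """Run the next-reaction simulation and summarize its steady state."""
    L = model.length
    lam = np.empty(L + 1)
    lam[0] = np.nan
    lam[1:] = model.lambdas
    lam[0] = lam[1]  # placeholder, never used: A-sites start at codon 2
    max_ribs = _max_ribs(L, model.footprint)

    (snaps, snap_n, dwell_sum, dwell_cnt, n_term, n_init, n_drop,
     t_elapsed) = run_tasep(
        np.int64(config.seed % (2 ** 31)),
        float(model.alpha),
        lam,
        np.int64(model.footprint),
        float(config.dropoff_rate),
        np.int64(max(1, config.burn_in_steps)),
        np.int64(config.n_samples),
        np.int64(config.sample_interval),
        np.int64(max_ribs),
    )

    n_snap = snaps.shape[0]
    occupancy = np.zeros(L + 1)
    if n_snap:
        flat = snaps[snaps > 0]
        occupancy = np.bincount(flat, minlength=L + 1).astype(float)
        occupancy /= n_snap
    site_occupancy = occupancy[1:]

    dwell = np.full(L, np.nan)
    seen = dwell_cnt[1:] > 0
    dwell[seen] = dwell_sum[1:][seen] / dwell_cnt[1:][seen]
    with np.errstate(divide="ignore"):
        obs_rate = np.where(seen, 1.0 / dwell, np.nan)

    # interference: among snapshots with an A-site at i, fraction that have
    # a trailing A-site exactly footprint codons behind
    interference = np.full(L, np.nan)
    if n_snap and snaps.shape[1] > 1:
        width = snaps.shape[1]
        valid = np.arange(width)[None, :] < snap_n[:, None]
        both = valid[:, 1:] & valid[:, :-1]
        at_min = both & (
            (snaps[:, 1:] - snaps[:, :-1]) == model.footprint
        )
        pair = np.bincount(
            snaps[:, 1:][at_min].ravel(), minlength=L + 1
        ).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            interference = np.where(
                occupancy[1:] > 0, pair[1:] / (occupancy[1:] * n_snap), np.nan
            )

    rho_total = float(snap_n.mean() / L) if n_snap else 0.0

    from .detection import stacked_mask

    if n_snap:
        valid, stacked = stacked_mask(snaps, snap_n, config.stack_threshold)
        rho_detected = (
            valid.sum() - (1.0 - config.detect_prob) * stacked.sum()
        ) / n_snap / L
    else:
        rho_detected = 0.0

    flux = n_term / t_elapsed if t_elapsed > 0 else 0.0
    return SimulationSummary(
        gene_id=model.gene_id,
        length=L,
        rho_total=rho_total,
        rho_detected=rho_detected,
        site_occupancy=site_occupancy,
        dwell_time=dwell,
        observed_rate=obs_rate,
        unobstructed_rate=model.lambdas.copy(),
        flux=flux,
        interference_prob=interference,
        snapshots=snaps,
        snapshot_counts=snap_n,
        n_terminations=int(n_term),
        n_initiations=int(n_init),
        n_dropoffs=int(n_drop),
        elapsed_time=float(t_elapsed),
    )


def observed_rates(summary: SimulationSummary) -> pd.DataFrame:
    """Per-position observed rate (1 / mean dwell) and the interference gap.

    The observed rate includes time spent blocked behind a downstream
    ribosome, so it is bounded above by the unobstructed rate; the
    returned ``gap`` column is ``unobstructed - observed``.  Positions a
    ribosome never visited are NaN.
    """
    return pd.DataFrame(
        {
            "position": np.arange(1, summary.length + 1),
            "observed_rate": summary.observed_rate,
            "unobstructed_rate": summary.unobstructed_rate,
            "gap": summary.unobstructed_rate - summary.observed_rate,
        }
    )


# ---------------------------------------------------------------------------
# exact stationary distribution for small systems
# ---------------------------------------------------------------------------

_STATE_GUARD = 100_000


def _enumerate_states(L: int, ell: int):
    """All admissible A-site configurations (ascending tuples, gaps > ell - 1)."""
    states = [()]
    frontier = [()]
    while frontier:
        new = []
        for cfg in frontier:
            lo = 2 if not cfg else cfg[-1] + ell
            for p in range(lo, L + 1):
                nxt = cfg + (p,)
                new.append(nxt)
        states.extend(new)
        frontier = new
        if len(states) > _STATE_GUARD:
            raise ValueError(
                f"configuration space exceeds {_STATE_GUARD} states; "
                "use simulate() instead"
            )
    return states


def exact_steady_state(model: GeneModel):
    """Solve the stationary master equation of the exclusion process.

    Returns ``(site_occupancy, flux)`` where ``site_occupancy[i - 1]`` is
    the stationary probability of an A-site at codon ``i`` and flux is
    the stationary termination rate.  Intended for small transcripts
    (state count guarded at 1e5); alpha == 0 is allowed and yields an
    empty lattice.
    """
    L = model.length
    ell = model.footprint
    lam = model.lambdas
    alpha = model.alpha if model.alpha > 0 else 0.0

    states = _enumerate_states(L, ell)
    index = {s: k for k, s in enumerate(states)}
    n = len(states)

    rows, cols, vals = [], [], []

    def add(src, dst, rate):
        rows.append(index[dst])
        cols.append(index[src])
        vals.append(rate)
        rows.append(index[src])
        cols.append(index[src])
        vals.append(-rate)

    for cfg in states:
        # initiation
        if alpha > 0 and (not cfg or cfg[0] >= 2 + ell):
            add(cfg, (2,) + cfg, alpha)
        for k, p in enumerate(cfg):
            if p == L:
                add(cfg, cfg[:k], lam[L - 1])  # termination (p is the max)
            else:
                blocked = k + 1 < len(cfg) and cfg[k + 1] - p <= ell
                if not blocked:
                    dst = cfg[:k] + (p + 1,) + cfg[k + 1:]
                    add(cfg, dst, lam[p - 1])

    Q = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    # replace one balance equation with the normalization constraint
    A = Q.tolil()
    A[0, :] = 1.0
    b = np.zeros(n)
    b[0] = 1.0
    pi = spsolve(A.tocsr(), b)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()

    occ = np.zeros(L)
    flux = 0.0
    for cfg, w in zip(states, pi):
        for p in cfg:
            occ[p - 1] += w
        if cfg and cfg[-1] == L:
            flux += w * lam[L - 1]
    return occ, flux


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_gene_model(model: GeneModel, path) -> None:
    """TSV with a ``#alpha=`` header and gene_id/position/codon/lambda rows."""
    with open(path, "w") as fh:
        fh.write(f"#alpha={model.alpha!r}\n")
        fh.write(f"#footprint={model.footprint}\n")
        df = pd.DataFrame(
            {
                "gene_id": model.gene_id,
                "position": np.arange(1, model.length + 1),
                "codon": list(model.codons),
                "lambda": model.lambdas,
            }
        )
        df.to_csv(fh, sep="\t", index=False)


def read_gene_model(path) -> GeneModel:
    header = {}
    with open(path) as fh:
        text = fh.readlines()
    body = []
    for line in text:
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            header[key] = value
        else:
            body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)), sep="\t")
    df = df.sort_values("position")
    return GeneModel(
        gene_id=str(df["gene_id"].iloc[0]),
        codons=tuple(df["codon"]),
        alpha=float(header["alpha"]),
        lambdas=df["lambda"].to_numpy(),
        footprint=int(header.get("footprint", DEFAULT_FOOTPRINT)),
    )


def write_snapshots(summary: SimulationSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_index\ta_site_positions\n")
        for k, (row, cnt) in enumerate(
            zip(summary.snapshots, summary.snapshot_counts)
        ):
            fh.write(f"{k}\t{','.join(map(str, row[:cnt]))}\n")
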