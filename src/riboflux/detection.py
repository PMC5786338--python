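"""Detection of closely stacked ribosomes and footprint-profile sampling.

Standard ribosome-profiling libraries select ~30-nt protected fragments,
so a pair of ribosomes whose A-sites are within 12 codons of each other
(free gap of at most 2 codons) protects a longer "disome" fragment and
may be missing from the library.  A :class:`DetectionScenario` states
the probability that such a closely stacked ribosome still contributes a
footprint: 1.0 (full detection), 0.5 (partial), 0.0 (none).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tasep import SimulationSummary

__all__ = [
    "DetectionScenario",
    "SCENARIOS",
    "classify_detected",
    "stacked_mask",
    "sample_profile",
    "expected_detected_profile",
    "densities",
]

DEFAULT_STACK_THRESHOLD = 12  # codons between consecutive A-sites


@dataclass(frozen=True)
class DetectionScenario:
    detect_prob: float
    stack_threshold: int = DEFAULT_STACK_THRESHOLD

    def __post_init__(self):
        if not 0.0 <= self.detect_prob <= 1.0:
            raise ValueError("detect_prob must be in [0, 1]")
        if self.stack_threshold < 1:
            raise ValueError("stack_threshold must be >= 1")


#: The three scenarios considered for stacked-ribosome omission.
SCENARIOS = {
    "full": DetectionScenario(1.0),
    "partial": DetectionScenario(0.5),
    "none": DetectionScenario(0.0),
}


def _stacked_flags(a_sites: np.ndarray, threshold: int) -> np.ndarray:
    """A ribosome is stacked iff either neighbour is within ``threshold``."""
    n = a_sites.shape[0]
    stacked = np.zeros(n, dtype=bool)
    if n > 1:
        gaps = np.diff(a_sites)
        stacked[:-1] |= gaps <= threshold
        stacked[1:] |= gaps <= threshold
    return stacked


def stacked_mask(
    snaps: np.ndarray, snap_n: np.ndarray, threshold: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-element (valid, stacked) masks for a snapshot array.

    ``snaps`` is (n_snap, max_ribs) with ascending positions padded by
    zeros; ``snap_n`` gives the ribosome count per row.
    """
    n_snap, width = snaps.shape
    valid = np.arange(width)[None, :] < snap_n[:, None]
    stacked = np.zeros_like(valid)
    if width > 1:
        both = valid[:, 1:] & valid[:, :-1]
        close = both & ((snaps[:, 1:] - snaps[:, :-1]) <= threshold)
        stacked[:, 1:] |= close
        stacked[:, :-1] |= close
    return valid, stacked


def classify_detected(
    a_sites, scenario: DetectionScenario, rng: np.random.Generator
) -> np.ndarray:
    """Per-ribosome detection flags for one configuration.

    ``a_sites`` must be strictly increasing A-site positions.  Stacked
    ribosomes (either neighbour within ``stack_threshold`` codons) are
    detected independently with probability ``detect_prob``; isolated
    ribosomes are always detected.  Both members of a stacked pair are
    candidates for non-detection.
    """
    a = np.asarray(a_sites)
    if a.ndim != 1:
        raise ValueError("a_sites must be one-dimensional")
    if a.size > 1 and not np.all(np.diff(a) > 0):
        raise ValueError("a_sites must be strictly increasing")
    stacked = _stacked_flags(a, scenario.stack_threshold)
    detected = np.ones(a.size, dtype=bool)
    if stacked.any():
        if scenario.detect_prob == 0.0:
            detected[stacked] = False
        elif scenario.detect_prob < 1.0:
            detected[stacked] = (
                rng.random(int(stacked.sum())) < scenario.detect_prob
            )
    return detected


def sample_profile(
    summary: SimulationSummary,
    scenario: DetectionScenario,
    rng: np.random.Generator,
    n_samples: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample footprint profiles from a snapshot stream.

    Per snapshot, detection flags are drawn, one A-site is drawn
    uniformly from the detected set (if nonempty) and added to the
    detected profile; independently one A-site drawn uniformly over all
    ribosomes is added to the total profile.  Snapshots are cycled until
    ``n_samples`` footprints have been collected for each profile
    (default: one pass over the stream).

    Returns ``(detected_counts, total_counts)``, each of length L with
    index 0 = codon 1.
    """
    L = summary.length
    detected_counts = np.zeros(L, dtype=np.int64)
    total_counts = np.zeros(L, dtype=np.int64)
    snaps, snap_n = summary.snapshots, summary.snapshot_counts
    n_snap = snaps.shape[0]
    if n_snap == 0 or not snap_n.any():
        warnings.warn("empty snapshot stream: returning empty profiles")
        return detected_counts, total_counts
    if n_samples is None:
        n_samples = n_snap

    valid, stacked = stacked_mask(snaps, snap_n, scenario.stack_threshold)

    def one_pass(detected):
        """One uniformly drawn position per snapshot with >=1 flagged
        ribosome, in stream order; returns the drawn positions."""
        ndet = detected.sum(axis=1)
        rows = ndet > 0
        if not rows.any():
            return np.empty(0, dtype=snaps.dtype)
        keys = np.where(detected[rows], rng.random(detected[rows].shape), -1.0)
        pick = keys.argmax(axis=1)
        return snaps[rows, :][np.arange(rows.sum()), pick]

    def collect(counts, flag_maker):
        got = 0
        guard = 0
        while got < n_samples:
            draws = one_pass(flag_maker())
            if draws.size == 0:
                guard += 1
                if guard > 2:
                    warnings.warn(
                        "no snapshot contains a detectable ribosome: "
                        "profile left incomplete"
                    )
                    return
                continue
            take = draws[: n_samples - got]
            counts += np.bincount(take - 1, minlength=L + 1)[:L]
            got += take.size

    collect(total_counts, lambda: valid)

    if scenario.detect_prob == 1.0:
        flag_maker = lambda: valid
    elif scenario.detect_prob == 0.0:
        flag_maker = lambda: valid & ~stacked
    else:
        flag_maker = lambda: valid & (
            ~stacked | (rng.random(snaps.shape) < scenario.detect_prob)
        )
    collect(detected_counts, flag_maker)
    return detected_counts, total_counts


def densities(
    summary: SimulationSummary, scenario: DetectionScenario
) -> pd.Series:
    """Total and detected ribosome densities (per codon and per 100 codons).

    The detected density marginalizes the Bernoulli detection draws
    exactly (expected detected count per snapshot), so it is a
    deterministic function of the snapshot stream.
    """
    L = summary.length
    snaps, snap_n = summary.snapshots, summary.snapshot_counts
    n_snap = snaps.shape[0]
    rho_total = float(snap_n.mean() / L) if n_snap else 0.0
    if n_snap == 0:
        rho_det = 0.0
    else:
        valid, stacked = stacked_mask(snaps, snap_n, scenario.stack_threshold)
        n_stacked = stacked.sum()
        rho_det = (
            valid.sum() - (1.0 - scenario.detect_prob) * n_stacked
        ) / n_snap / L
    return pd.Series(
        {
            "rho_total": rho_total,
            "rho_detected": rho_det,
            "rho_total_per100": 100 * rho_total,
            "rho_detected_per100": 100 * rho_det,
        }
    )


def expected_detected_profile(
    summary: SimulationSummary,
    scenario: DetectionScenario,
    rng: np.random.Generator,
) -> np.ndarray:
    """Detected footprint distribution with the uniform pick marginalized.

    For each snapshot, detection flags are drawn once; every detected
    ribosome then receives weight ``1 / n_detected`` (the expectation of
    the one-footprint-per-snapshot sampling scheme conditional on the
    flags).  For detect_prob 0 or 1 the result is a deterministic
    function of the snapshot stream.  Returns a length-L vector
    normalized to sum 1 (all-zero if nothing is ever detected).
    """
    L = summary.length
    snaps, snap_n = summary.snapshots, summary.snapshot_counts
    out = np.zeros(L)
    if snaps.shape[0] == 0:
        return out
    valid, stacked = stacked_mask(snaps, snap_n, scenario.stack_threshold)
    detected = valid.copy()
    if scenario.detect_prob == 0.0:
        detected &= ~stacked
    elif scenario.detect_prob < 1.0:
        keep = rng.random(snaps.shape) < scenario.detect_prob
        detected &= ~stacked | keep
    ndet = detected.sum(axis=1)
    rows = ndet > 0
    if not rows.any():
        return out
    w = np.where(detected[rows], 1.0 / ndet[rows][:, None], 0.0)
    np.add.at(out, snaps[rows].ravel() - 1, w.ravel() * detected[rows].ravel())
    return out / out.sum()
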