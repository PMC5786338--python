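"""Ribosomal drop-off rate estimation from footprint-density decay.

If a ribosome prematurely unbinds with probability ``r`` per codon per
elongation event, the ribosome flux (and hence the mean footprint
density) decays geometrically along the ORF: binning the ORF into
``bin_size``-codon bins, the bin-averaged normalized read count follows
``A * exp(-Q * X)`` in the bin index ``X``, with per-codon survival
``(1 - r) ** bin_size = exp(-Q)``.  Fitting log bin means by ordinary
least squares gives Q, and ``r = 1 - exp(-Q / bin_size)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DropoffFit",
    "bin_log_means",
    "fit_decay",
    "q_to_rate",
    "survival",
    "estimate_dropoff",
]


@dataclass
class DropoffFit:
    bin_size: int
    region: tuple[int, int]
    A: float
    Q: float
    r: float
    bootstrap_Q: np.ndarray | None = None


def _gene_bin_means(counts, bin_size, region):
    """Per-bin means of a gene's mean-normalized counts, NaN-padded."""
    counts = np.asarray(counts, dtype=float)
    lo, hi = region
    if counts.size < hi:
        return None
    norm = counts / counts.mean() if counts.mean() > 0 else None
    if norm is None:
        return None
    seg = norm[lo - 1: hi]
    n_bins = seg.size // bin_size
    if n_bins < 1:
        return None
    return seg[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)


def bin_log_means(
    profiles: dict[str, np.ndarray],
    bin_size: int = 25,
    region: tuple[int, int] = (25, 225),
) -> np.ndarray:
    """Log of the cross-gene average normalized read count per bin.

    Each gene's counts are normalized by the gene mean, averaged within
    ``bin_size``-codon bins over ``region`` (1-based, inclusive-exclusive
    on the last partial bin), then averaged across genes; the log of the
    bin average is returned.  Genes shorter than the region are skipped.
    """
    rows = [
        m
        for m in (
            _gene_bin_means(c, bin_size, region) for c in profiles.values()
        )
        if m is not None
    ]
    if not rows:
        raise ValueError("no gene covers the requested region")
    means = np.vstack(rows).mean(axis=0)
    keep = means > 0
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} empty bins")
    return np.log(means[keep])


def fit_decay(log_bin_values: np.ndarray) -> tuple[float, float]:
    """OLS of log bin value on 1-based bin index; returns (A, Q).

    The model is ``value = A * exp(-Q * X)``; Q is minus the slope and A
    the exponential of the intercept.
    """
    y = np.asarray(log_bin_values, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 bins")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite log bin values")
    x = np.arange(1, y.size + 1, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return float(np.exp(intercept)), float(-slope)


def q_to_rate(Q: float, bin_size: int = 25) -> float:
    """Per-codon, per-elongation-event drop-off probability from Q.

    Per-codon survival ``1 - r`` compounds to ``exp(-Q)`` over one bin:
    ``r = 1 - exp(-Q / bin_size)``.  Negative Q (density increasing
    along the ORF) yields r = 0 with a warning.
    """
    if Q < 0:
        warnings.warn("negative decay coefficient; drop-off rate set to 0")
        return 0.0
    return float(1.0 - np.exp(-Q / bin_size))


def survival(r: float, n_codons: int) -> float:
    """Probability that a ribosome survives ``n_codons`` elongation steps."""
    if not 0.0 <= r < 1.0:
        raise ValueError("drop-off rate must be in [0, 1)")
    if n_codons < 0:
        raise ValueError("codon count must be non-negative")
    return float((1.0 - r) ** n_codons)


def estimate_dropoff(
    profiles: dict[str, np.ndarray],
    bin_size: int = 25,
    region: tuple[int, int] = (25, 225),
    n_bootstrap: int = 0,
    rng: np.random.Generator | None = None,
) -> DropoffFit:
    """Full drop-off estimate, optionally with a gene-level bootstrap.

    The bootstrap resamples genes with replacement and refits, giving
    the sampling distribution of Q.
    """
    logs = bin_log_means(profiles, bin_size, region)
    A, Q = fit_decay(logs)
    boot = None
    if n_bootstrap > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        ids = list(profiles)
        qs = []
        for _ in range(n_bootstrap):
            pick = rng.integers(len(ids), size=len(ids))
            sub = {f"b{j}": profiles[ids[k]] for j, k in enumerate(pick)}
            try:
                _, qb = fit_decay(bin_log_means(sub, bin_size, region))
            except ValueError:
                continue
            qs.append(qb)
        boot = np.asarray(qs)
    return DropoffFit(
        bin_size=bin_size,
        region=region,
        A=A,
        Q=Q,
        r=q_to_rate(Q, bin_size),
        bootstrap_Q=boot,
    )
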