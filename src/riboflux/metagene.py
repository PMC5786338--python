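"""Position-aligned (metagene) averages across gene sets.

All operators are equal-gene-weight averages over whatever genes cover a
position: normalized footprint-density ramps, codon-group frequency
curves, positional mean elongation rates, observed/unobstructed rate
gaps, and charged-residue frequency curves.  Start-aligned coordinates
are positive 1-based codon positions; stop-aligned coordinates are
negative with -1 = the stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import NEGATIVE_RESIDUES, POSITIVE_RESIDUES

__all__ = [
    "MetageneCurve",
    "ramp_profile",
    "codon_group_frequencies",
    "positional_mer",
    "rate_gap_curves",
    "charge_frequency_metagene",
    "smooth_curve",
    "DEFAULT_MER_BIN_EDGES",
]

DEFAULT_MER_BIN_EDGES = (4.0, 6.0, 8.0, 10.0, 12.0, np.inf)


@dataclass
class MetageneCurve:
    positions: np.ndarray  # start-aligned positive or stop-aligned negative
    value: np.ndarray
    n_genes: np.ndarray
    smoothing: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "value": self.value,
             "n": self.n_genes}
        )


def smooth_curve(values: np.ndarray, half_width: int) -> np.ndarray:
    """Moving average over ±half_width, truncated at the ends.

    Linear and constant-preserving; NaNs are ignored within each window.
    """
    if half_width <= 0:
        return np.asarray(values, dtype=float).copy()
    v = np.asarray(values, dtype=float)
    out = np.full_like(v, np.nan)
    for i in range(v.size):
        w = v[max(0, i - half_width): i + half_width + 1]
        w = w[np.isfinite(w)]
        if w.size:
            out[i] = w.mean()
    return out


def _align_slices(length: int, align: str, max_pos: int):
    """Map a gene of ``length`` codons onto aligned coordinates."""
    n = min(length, max_pos)
    if align == "start":
        return slice(0, n), slice(0, n)
    if align == "stop":
        # output index 0 = position -max_pos, last index = position -1
        return slice(max_pos - n, max_pos), slice(length - n, length)
    raise ValueError("align must be 'start' or 'stop'")


def _aligned_positions(align: str, max_pos: int) -> np.ndarray:
    if align == "start":
        return np.arange(1, max_pos + 1)
    return np.arange(-max_pos, 0)


def _mean_over_genes(tracks, align, max_pos, smoothing=0) -> MetageneCurve:
    acc = np.zeros(max_pos)
    cnt = np.zeros(max_pos)
    for track in tracks:
        track = np.asarray(track, dtype=float)
        out_sl, in_sl = _align_slices(track.size, align, max_pos)
        vals = track[in_sl]
        ok = np.isfinite(vals)
        acc[out_sl][ok] += vals[ok]
        cnt[out_sl][ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    if smoothing:
        mean = smooth_curve(mean, smoothing)
    return MetageneCurve(
        positions=_aligned_positions(align, max_pos),
        value=mean,
        n_genes=cnt.astype(int),
        smoothing=smoothing,
    )


def ramp_profile(
    profiles: dict[str, np.ndarray],
    align: str = "start",
    max_pos: int = 200,
    smoothing: int = 0,
) -> MetageneCurve:
    """Metagene relative normalized footprint density.

    Each gene's profile is normalized by its own mean over informative
    (count > 0) positions, then averaged with equal gene weight per
    aligned position; uniform coverage gives a flat curve at 1.
    """
    tracks = []
    for counts in profiles.values():
        counts = np.asarray(counts, dtype=float)
        informative = counts > 0
        if not informative.any():
            continue
        tracks.append(counts / counts[informative].mean())
    return _mean_over_genes(tracks, align, max_pos, smoothing)


def codon_group_frequencies(
    sequences: dict[str, tuple[str, ...]],
    mer_by_codon: dict[str, float],
    bin_edges=DEFAULT_MER_BIN_EDGES,
    max_pos: int = 200,
    smoothing: int = 0,
) -> list[MetageneCurve]:
    """Per-position frequency of codons in each mean-elongation-rate bin.

    Codons are binned into half-open intervals [edge_k, edge_k+1) of
    their MER; stop codons (absent from ``mer_by_codon``) are excluded
    from both numerator and denominator.  At each position the group
    frequencies sum to 1 over genes covering that position.
    """
    edges = np.asarray(bin_edges, dtype=float)
    n_groups = edges.size - 1

    def group_of(codon):
        mer = mer_by_codon.get(codon)
        if mer is None:
            return None
        k = int(np.searchsorted(edges, mer, side="right")) - 1
        if k < 0 or k >= n_groups:
            return None
        return k

    tracks = {k: [] for k in range(n_groups)}
    for codons in sequences.values():
        groups = [group_of(c) for c in codons]
        for k in range(n_groups):
            tracks[k].append(
                np.array(
                    [np.nan if g is None else float(g == k) for g in groups]
                )
            )
    return [
        _mean_over_genes(tracks[k], "start", max_pos, smoothing)
        for k in range(n_groups)
    ]


def positional_mer(
    rates_by_gene: dict[str, np.ndarray],
    codons_by_gene: dict[str, tuple[str, ...]],
    window: int = 20,
    max_pos: int = 300,
) -> pd.DataFrame:
    """Positional mean elongation rate per codon type, smoothed ±window.

    Returns a frame with one smoothed curve per codon type, the
    frequency-weighted overall curve, and the codon-frequency-only
    counterfactual in which every codon elongates at its global MER
    (isolating the contribution of codon composition to positional
    speed variation).
    """
    # global codon MERs
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for gid, lam in rates_by_gene.items():
        for codon, rate in zip(codons_by_gene[gid], lam):
            sums[codon] = sums.get(codon, 0.0) + float(rate)
            counts[codon] = counts.get(codon, 0) + 1
    mer = {c: sums[c] / counts[c] for c in sums}

    codon_types = sorted(mer)
    per_type_acc = {c: np.zeros(max_pos) for c in codon_types}
    per_type_cnt = {c: np.zeros(max_pos) for c in codon_types}
    overall_acc = np.zeros(max_pos)
    counterfactual_acc = np.zeros(max_pos)
    overall_cnt = np.zeros(max_pos)
    for gid, lam in rates_by_gene.items():
        codons = codons_by_gene[gid]
        n = min(max_pos, len(codons))
        for i in range(n):
            c = codons[i]
            if c not in mer:
                continue
            per_type_acc[c][i] += lam[i]
            per_type_cnt[c][i] += 1
            overall_acc[i] += lam[i]
            counterfactual_acc[i] += mer[c]
            overall_cnt[i] += 1

    def finalize(acc, cnt):
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        return smooth_curve(raw, window)

    data = {"position": np.arange(1, max_pos + 1)}
    for c in codon_types:
        data[c] = finalize(per_type_acc[c], per_type_cnt[c])
    data["weighted_mean"] = finalize(overall_acc, overall_cnt)
    data["codon_usage_only"] = finalize(counterfactual_acc, overall_cnt)
    return pd.DataFrame(data)


def rate_gap_curves(
    summaries: list,
    align: str = "start",
    max_pos: int = 300,
) -> pd.DataFrame:
    """Mean unobstructed and observed rates per aligned position.

    The gap (unobstructed - observed) quantifies the slowdown caused by
    ribosomal interference; with slow termination it peaks one footprint
    upstream of the stop codon, where trailing ribosomes queue.
    """
    unobstructed = _mean_over_genes(
        [s.unobstructed_rate for s in summaries], align, max_pos
    )
    observed = _mean_over_genes(
        [s.observed_rate for s in summaries], align, max_pos
    )
    return pd.DataFrame(
        {
            "position": unobstructed.positions,
            "unobstructed": unobstructed.value,
            "observed": observed.value,
            "gap": unobstructed.value - observed.value,
            "n": unobstructed.n_genes,
        }
    )


def charge_frequency_metagene(
    protein_sequences: dict[str, str],
    max_pos: int = 200,
    window: int = 10,
    min_len: int = 200,
) -> pd.DataFrame:
    """Positional frequency of positive (K/R) and negative (D/E) residues.

    Genes shorter than ``min_len`` codons are excluded; ambiguous or
    non-standard residues count toward neither charge class (but do
    count toward the per-position denominator).  Returns raw and
    ±window/2-smoothed curves.
    """
    half = window // 2
    pos_tracks, neg_tracks = [], []
    for seq in protein_sequences.values():
        if len(seq) < min_len:
            continue
        pos_tracks.append(
            np.array([1.0 if r in POSITIVE_RESIDUES else 0.0 for r in seq])
        )
        neg_tracks.append(
            np.array([1.0 if r in NEGATIVE_RESIDUES else 0.0 for r in seq])
        )
    if not pos_tracks:
        raise ValueError(f"no sequences of length >= {min_len}")
    pos_curve = _mean_over_genes(pos_tracks, "start", max_pos)
    neg_curve = _mean_over_genes(neg_tracks, "start", max_pos)
    return pd.DataFrame(
        {
            "position": pos_curve.positions,
            "positive": pos_curve.value,
            "negative": neg_curve.value,
            "positive_smooth": smooth_curve(pos_curve.value, half),
            "negative_smooth": smooth_curve(neg_curve.value, half),
            "n": pos_curve.n_genes,
        }
    )
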