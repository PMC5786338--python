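"""Linear models of positional elongation-rate variation.

The dependent variable at codon position ``i`` is the mean deviation of
the inferred elongation rate from its codon-type-specific average,

    y_i = < lambda_i^g  -  lambda_bar_c(g, i) >_g ,

averaged over the gene set.  Explanatory variables are windowed
aggregates of nascent-peptide and mRNA properties, averaged over genes:
counts of positively (K/R) or negatively (D/E) charged residues in a
window upstream of the A-site, mean Kyte-Doolittle hydropathy upstream,
and mean PARS (mRNA secondary-structure) score downstream.  An upstream
window ``[a:b]`` at A-site ``i`` covers positions ``i-b .. i-a``; a
downstream window covers ``i+a .. i+b``; both ends inclusive, truncated
at the ORF boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = [
    "FeatureSpec",
    "RegressionResult",
    "KYTE_DOOLITTLE",
    "POSITIVE_RESIDUES",
    "NEGATIVE_RESIDUES",
    "gene_feature_track",
    "mean_rate_deviation",
    "compute_feature",
    "fit_linear",
    "scan_windows",
]

POSITIVE_RESIDUES = frozenset("KR")
NEGATIVE_RESIDUES = frozenset("DE")

#: Kyte & Doolittle hydropathy index per residue.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

KINDS = ("negative_charge", "positive_charge", "hydropathy", "pars")
_UPSTREAM = {"negative_charge", "positive_charge", "hydropathy"}
_COUNT = {"negative_charge", "positive_charge"}


@dataclass(frozen=True)
class FeatureSpec:
    kind: str
    window: tuple[int, int]  # inclusive offsets [a:b]

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        a, b = self.window
        if not 0 <= a <= b:
            raise ValueError("window must satisfy 0 <= a <= b")

    @property
    def side(self) -> str:
        return "upstream" if self.kind in _UPSTREAM else "downstream"

    @property
    def aggregation(self) -> str:
        return "count" if self.kind in _COUNT else "mean"


@dataclass
class RegressionResult:
    betas: dict[str, float]
    intercept: float
    r_squared: float
    fitted: np.ndarray
    region: tuple[int, int]
    condition_number: float


def _per_position_values(kind: str, gene) -> np.ndarray:
    """Raw per-position track for one gene (before windowing).

    ``gene`` is a protein sequence (string, one residue per codon
    position, 'X'/'*' ignored) for charge and hydropathy kinds, or a
    per-codon score array for 'pars'.
    """
    if kind == "pars":
        return np.asarray(gene, dtype=float)
    seq = str(gene)
    if kind == "hydropathy":
        return np.array([KYTE_DOOLITTLE.get(r, np.nan) for r in seq])
    residues = (
        POSITIVE_RESIDUES if kind == "positive_charge" else NEGATIVE_RESIDUES
    )
    return np.array([1.0 if r in residues else 0.0 for r in seq])


def gene_feature_track(gene, spec: FeatureSpec) -> np.ndarray:
    """Windowed aggregate at every A-site position of a single gene.

    Windows extending past the ORF ends are truncated to the available
    positions; counts count what is there, means average what is there.
    Positions whose window is entirely outside the gene are NaN.
    """
    vals = _per_position_values(spec.kind, gene)
    L = vals.size
    finite = np.isfinite(vals)
    cs = np.concatenate(([0.0], np.cumsum(np.where(finite, vals, 0.0))))
    cn = np.concatenate(([0], np.cumsum(finite.astype(int))))
    a, b = spec.window
    i = np.arange(1, L + 1)
    if spec.side == "upstream":
        lo = np.maximum(i - b, 1)
        hi = np.minimum(i - a, L)
    else:
        lo = np.maximum(i + a, 1)
        hi = np.minimum(i + b, L)
    empty = hi < lo
    lo_c = np.clip(lo, 1, L)
    hi_c = np.clip(hi, 1, L)
    total = cs[hi_c] - cs[lo_c - 1]
    count = cn[hi_c] - cn[lo_c - 1]
    total[empty] = 0.0
    count[empty] = 0
    if spec.aggregation == "count":
        # a truncated or empty window simply counts what is there
        return total
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return np.where(empty | (count == 0), np.nan, out)


def compute_feature(
    genes: dict[str, object], spec: FeatureSpec, max_pos: int
) -> np.ndarray:
    """x_{i,k}: mean over genes of the per-gene window aggregate.

    ``genes`` maps gene id to protein sequence (charge/hydropathy) or
    per-codon PARS array.  Positions past a gene's end are excluded from
    that position's average.  Returns a vector for positions 1..max_pos.
    """
    acc = np.zeros(max_pos)
    cnt = np.zeros(max_pos)
    for gene in genes.values():
        track = gene_feature_track(gene, spec)[:max_pos]
        ok = np.isfinite(track)
        acc[: track.size][ok] += track[ok]
        cnt[: track.size][ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)


def mean_rate_deviation(
    rates_by_gene: dict[str, np.ndarray],
    codons_by_gene: dict[str, tuple[str, ...]],
    max_pos: int,
) -> np.ndarray:
    """Positional mean deviation of rates from codon-type averages.

    The codon-type average is taken over all genes and positions; the
    deviation at position ``i`` is then averaged over the genes long
    enough to have that position.  NaN where no gene covers a position.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for gid, lam in rates_by_gene.items():
        for codon, rate in zip(codons_by_gene[gid], lam):
            sums[codon] = sums.get(codon, 0.0) + float(rate)
            counts[codon] = counts.get(codon, 0) + 1
    codon_mean = {c: sums[c] / counts[c] for c in sums}

    acc = np.zeros(max_pos)
    cnt = np.zeros(max_pos)
    for gid, lam in rates_by_gene.items():
        codons = codons_by_gene[gid]
        n = min(max_pos, len(codons))
        dev = np.array(
            [lam[i] - codon_mean[codons[i]] for i in range(n)]
        )
        acc[:n] += dev
        cnt[:n] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)


def _design(x_cols: list[np.ndarray], region, y: np.ndarray):
    i0, i1 = region
    sl = slice(i0 - 1, i1)
    X = np.column_stack([c[sl] for c in x_cols])
    yy = y[sl]
    ok = np.isfinite(yy) & np.all(np.isfinite(X), axis=1)
    return X[ok], yy[ok]


def fit_linear(
    y: np.ndarray,
    x_table: dict[str, np.ndarray],
    region: tuple[int, int],
    intercept: bool = True,
) -> RegressionResult:
    """Ordinary least squares of y on the feature columns over a region.

    ``region`` is an inclusive 1-based codon-position interval.  A large
    design condition number (collinear features) triggers a warning.
    """
    names = list(x_table)
    X, yy = _design([x_table[k] for k in names], region, y)
    if X.shape[0] <= X.shape[1] + int(intercept):
        raise ValueError("not enough positions in region for the fit")
    Xd = sm.add_constant(X) if intercept else X
    model = sm.OLS(yy, Xd).fit()
    cond = float(np.linalg.cond(Xd))
    if cond > 1e8:
        warnings.warn(
            f"ill-conditioned design (cond={cond:.2e}); "
            "features may be collinear"
        )
    params = model.params
    if intercept:
        icept, betas = float(params[0]), params[1:]
    else:
        icept, betas = 0.0, params
    return RegressionResult(
        betas=dict(zip(names, map(float, betas))),
        intercept=icept,
        r_squared=float(model.rsquared),
        fitted=np.asarray(model.fittedvalues),
        region=region,
        condition_number=cond,
    )


def _window_grid(a_max: int, b_max: int) -> list[tuple[int, int]]:
    grid = [
        (a, b) for a in range(0, a_max + 1) for b in range(a, b_max + 1)
    ]
    # tie-break order: smaller width first, then smaller a
    grid.sort(key=lambda w: (w[1] - w[0], w[0]))
    return grid


def _feature_matrix(genes, kind, grid, max_pos):
    """Stack compute_feature over all candidate windows (rows)."""
    rows = np.empty((len(grid), max_pos))
    # windowed means/counts share per-gene cumulative sums; recompute per
    # window is O(genes * L) each and fast enough at these grid sizes
    for r, (a, b) in enumerate(grid):
        rows[r] = compute_feature(genes, FeatureSpec(kind, (a, b)), max_pos)
    return rows


def scan_windows(
    y: np.ndarray,
    genes_by_kind: dict[str, dict[str, object]],
    region: tuple[int, int],
    a_max: int = 15,
    b_max: int = 45,
    intercept: bool = True,
) -> tuple[dict[str, FeatureSpec], RegressionResult]:
    """Exhaustive window search maximizing R-squared over a region.

    ``genes_by_kind`` maps each feature kind to its gene inputs (protein
    sequences, or PARS arrays for 'pars').  One or two kinds are scanned
    by exhaustive joint enumeration; three or more by coordinate ascent
    from each kind's best single window (each sweep is exhaustive in one
    kind).  Ties are broken toward smaller windows.
    """
    kinds = list(genes_by_kind)
    if not kinds:
        raise ValueError("no feature kinds to scan")
    max_pos = region[1]
    grid = _window_grid(a_max, b_max)
    mats = {
        k: _feature_matrix(genes_by_kind[k], k, grid, max_pos)
        for k in kinds
    }

    i0, i1 = region
    sl = slice(i0 - 1, i1)
    yy = y[sl]
    ok = np.isfinite(yy)
    for k in kinds:
        ok &= np.all(np.isfinite(mats[k][:, sl]), axis=0)
    yy = yy[ok]
    Z = {k: mats[k][:, sl][:, ok] for k in kinds}
    n = yy.size
    if n < len(kinds) + 2:
        raise ValueError("region too short for the scan")

    yc = yy - yy.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm == 0:
        raise ValueError("dependent variable is constant over the region")
    yu = yc / ynorm

    def center_norm(M):
        Mc = M - M.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Mc, axis=1)
        good = norms > 1e-12
        Mu = np.zeros_like(Mc)
        Mu[good] = Mc[good] / norms[good][:, None]
        return Mu, good

    units = {}
    usable = {}
    for k in kinds:
        units[k], usable[k] = center_norm(Z[k])

    best: dict[str, int] = {}
    if len(kinds) == 1:
        k = kinds[0]
        r = units[k] @ yu
        r2 = np.where(usable[k], r ** 2, -np.inf)
        best[k] = int(np.argmax(r2))
    elif len(kinds) == 2:
        k1, k2 = kinds
        r1 = units[k1] @ yu
        r2v = units[k2] @ yu
        r12 = units[k1] @ units[k2].T
        denom = 1.0 - r12 ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            R2 = (
                r1[:, None] ** 2
                + r2v[None, :] ** 2
                - 2.0 * r1[:, None] * r2v[None, :] * r12
            ) / denom
        R2[denom < 1e-10] = -np.inf
        R2[~usable[k1], :] = -np.inf
        R2[:, ~usable[k2]] = -np.inf
        flat = int(np.argmax(R2))
        best[k1], best[k2] = np.unravel_index(flat, R2.shape)
        best = {k: int(v) for k, v in best.items()}
    else:
        # coordinate ascent, each sweep exhaustive in one kind
        for k in kinds:
            r = units[k] @ yu
            r2 = np.where(usable[k], r ** 2, -np.inf)
            best[k] = int(np.argmax(r2))
        for _ in range(10):
            changed = False
            for k in kinds:
                others = [Z[o][best[o]] for o in kinds if o != k]
                r2best, ibest = -np.inf, best[k]
                for idx in range(len(grid)):
                    if not usable[k][idx]:
                        continue
                    cols = [Z[k][idx]] + ([c for c in others])
                    X = sm.add_constant(np.column_stack(cols))
                    beta, res, rank, _ = np.linalg.lstsq(X, yy, rcond=None)
                    resid = yy - X @ beta
                    r2 = 1.0 - resid @ resid / (ynorm ** 2)
                    if r2 > r2best + 1e-12:
                        r2best, ibest = r2, idx
                if ibest != best[k]:
                    best[k] = ibest
                    changed = True
            if not changed:
                break

    specs = {k: FeatureSpec(k, grid[best[k]]) for k in kinds}
    x_table = {
        k: compute_feature(genes_by_kind[k], specs[k], max_pos)
        for k in kinds
    }
    result = fit_linear(y, x_table, region, intercept=intercept)
    return specs, result
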