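"""Ribosome exit-tunnel geometry and potentials.

The tunnel centerline (exported by tunnel-detection software as ordered
3-D samples with a local radius) is well approximated by a straight
line, so the dynamics of a particle inside it reduce to one-dimensional
diffusion along the arc coordinate ``x`` (PTC at x = 0) in two
potentials: the entropic potential ``S(x) = ln(pi r(x)^2)`` arising from
the varying cross-section, and a Coulomb potential summed over nearby
ribosomal charges (phosphate groups and charged side chains) weighted by
inverse distance.  Negative gradients of the smoothed potentials give
the corresponding longitudinal forces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TunnelProfile",
    "ChargeSet",
    "fit_centerline",
    "charges_from_structure",
    "read_pdb_atoms",
    "entropic_potential",
    "coulomb_potential",
    "read_centerline_csv",
]

#: representative charged atoms: residue name -> (atom name, charge in e)
_CHARGE_RULES = {
    "LYS": ("NZ", +1.0),
    "ARG": ("CZ", +1.0),
    "ASP": ("CG", -1.0),
    "GLU": ("CD", -1.0),
}
#: nucleotide residue names carrying a backbone phosphate (charge -1 at P)
_NUCLEOTIDES = {
    "A", "C", "G", "U", "DA", "DC", "DG", "DT",
    "ADE", "CYT", "GUA", "URA", "THY",
}
#: recognized but deliberately neutral (histidine: standard-pH assumption)
_NEUTRAL = {
    "ALA", "CYS", "PHE", "GLY", "HIS", "ILE", "LEU", "MET", "ASN",
    "PRO", "GLN", "SER", "THR", "VAL", "TRP", "TYR", "HOH", "MG",
    "ZN", "NA", "CL",
}


@dataclass
class TunnelProfile:
    """Ordered centerline samples from the PTC (x = 0) to the exit."""

    centerline: np.ndarray  # (n, 3) coordinates, Angstrom
    radius: np.ndarray      # r(x) > 0, Angstrom
    x: np.ndarray           # arc coordinate, strictly increasing, Angstrom

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if not np.all(np.diff(self.x) > 0):
            raise ValueError("arc coordinate must be strictly increasing")
        if np.any(self.radius <= 0):
            raise ValueError("radii must be positive")


@dataclass
class ChargeSet:
    positions: np.ndarray  # (n, 3), Angstrom
    charges: np.ndarray    # elementary units

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.charges = np.asarray(self.charges, dtype=float)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("charge coordinates must be finite")

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def __add__(self, other: "ChargeSet") -> "ChargeSet":
        return ChargeSet(
            np.vstack([self.positions, other.positions]),
            np.concatenate([self.charges, other.charges]),
        )


def fit_centerline(points: np.ndarray):
    """Total-least-squares line through 3-D points (first principal axis).

    Returns ``(origin, direction, r_squared, arc)`` where ``r_squared``
    is the fraction of total variance explained by the principal axis
    and ``arc`` is the projection of each point onto the line, shifted
    so the first point (PTC end) is at 0 and oriented toward the last.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("need at least 3 three-dimensional points")
    center = pts.mean(axis=0)
    rel = pts - center
    cov = rel.T @ rel
    if not cov.any():
        raise ValueError("points are coincident")
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, -1]
    r_squared = float(evals[-1] / evals.sum())
    arc = rel @ direction
    if arc[-1] < arc[0]:
        direction = -direction
        arc = -arc
    arc = arc - arc[0]
    return center, direction, r_squared, arc


def read_pdb_atoms(path) -> pd.DataFrame:
    """ATOM/HETATM records from a PDB-format file.

    Returns a frame with atom_name, residue_name, chain, residue_number
    and coordinates; the fixed-column PDB layout is parsed directly.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith(("ATOM", "HETATM")):
                continue
            rows.append(
                {
                    "atom_name": line[12:16].strip(),
                    "residue_name": line[17:20].strip(),
                    "chain": line[21].strip(),
                    "residue_number": int(line[22:26]),
                    "x": float(line[30:38]),
                    "y": float(line[38:46]),
                    "z": float(line[46:54]),
                }
            )
    return pd.DataFrame(rows)


def charges_from_structure(atoms: pd.DataFrame) -> ChargeSet:
    """Point charges at representative atoms of a structure.

    -1 at each nucleotide phosphorus (backbone phosphate), +1 at LYS NZ
    and ARG CZ, -1 at ASP CG and GLU CD; histidine and everything else
    uncharged.  Residue names matching neither rule are counted and
    reported in a warning (they simply carry no charge).
    """
    pos, q = [], []
    known = set(_CHARGE_RULES) | _NUCLEOTIDES | _NEUTRAL
    unknown: set[str] = set()
    for row in atoms.itertuples(index=False):
        resn = row.residue_name
        if resn in _NUCLEOTIDES:
            if row.atom_name == "P":
                pos.append((row.x, row.y, row.z))
                q.append(-1.0)
        elif resn in _CHARGE_RULES:
            atom, charge = _CHARGE_RULES[resn]
            if row.atom_name == atom:
                pos.append((row.x, row.y, row.z))
                q.append(charge)
        elif resn not in known:
            unknown.add(resn)
    if unknown:
        warnings.warn(
            f"{len(unknown)} residue names carried no charge rule: "
            f"{sorted(unknown)[:10]}"
        )
    if not pos:
        return ChargeSet(np.empty((0, 3)), np.empty(0))
    return ChargeSet(np.array(pos), np.array(q))


def _smooth_on_grid(values: np.ndarray, x: np.ndarray, width: float):
    """Moving average over a +-width/2 window in x units."""
    out = np.empty_like(values)
    half = width / 2.0
    for i, xi in enumerate(x):
        sel = (x >= xi - half) & (x <= xi + half)
        out[i] = values[sel].mean()
    return out


def entropic_potential(
    profile: TunnelProfile, smooth: float = 10.0
) -> pd.DataFrame:
    """S(x) = ln(pi r(x)^2) and its smoothed negative gradient.

    The gradient is computed by central finite differences on the arc
    coordinate and smoothed with a ``smooth``-Angstrom moving average.
    """
    S = np.log(np.pi * profile.radius ** 2)
    dS = np.gradient(S, profile.x)
    return pd.DataFrame(
        {
            "x": profile.x,
            "S": S,
            "dS_dx": dS,
            "neg_grad_S": _smooth_on_grid(-dS, profile.x, smooth),
        }
    )


def coulomb_potential(
    profile: TunnelProfile,
    charges: ChargeSet,
    cutoff: float = 20.0,
    smooth: float = 10.0,
) -> pd.DataFrame:
    """Coulomb potential along the centerline from nearby charges.

    ``V(x) = sum_j q_j / d(x, j)`` over charges within ``cutoff``
    Angstrom of the centerline point at ``x`` (unit prefactor; the
    potential is in arbitrary units).  Charges coincident with a
    centerline point are excluded with a warning.
    """
    if charges.charges.size == 0:
        raise ValueError("charge set is empty")
    d = np.linalg.norm(
        profile.centerline[:, None, :] - charges.positions[None, :, :],
        axis=2,
    )
    zero = d == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.any(axis=0).sum())} charge(s) coincide with a "
            "centerline point; excluded"
        )
    with np.errstate(divide="ignore"):
        contrib = np.where(
            (d <= cutoff) & ~zero, charges.charges[None, :] / d, 0.0
        )
    V = contrib.sum(axis=1)
    dV = np.gradient(V, profile.x)
    return pd.DataFrame(
        {
            "x": profile.x,
            "V": V,
            "dV_dx": dV,
            "neg_grad_V": _smooth_on_grid(-dV, profile.x, smooth),
        }
    )


def read_centerline_csv(path) -> TunnelProfile:
    """Centerline CSV (x, y, z, radius) as exported by tunnel software.

    The arc coordinate is the cumulative distance along the ordered
    samples, starting at 0 at the first (PTC) sample.
    """
    df = pd.read_csv(path)
    pts = df[["x", "y", "z"]].to_numpy(float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate(([0.0], np.cumsum(seg)))
    return TunnelProfile(
        centerline=pts, radius=df["radius"].to_numpy(float), x=arc
    )
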