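"""Readers, writers, A-site assignment, gene filtering and TE calibration.

Footprint reads of 28-30 nt are assigned an A-site codon from their
length and reading-frame shift; genes are filtered on length and
coverage; translation efficiency (TE = footprint RPKM / mRNA RPKM) is
calibrated against polysome-gradient ribosome densities by a
through-origin linear fit on the low-density subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReadRecord",
    "TERecord",
    "asite_nt_position",
    "map_read",
    "filter_genes",
    "fit_te_scaling",
    "TEScaling",
    "read_coding_fasta",
    "read_read_records",
    "write_read_records",
    "reads_to_profiles",
    "read_profiles",
    "write_profiles",
    "read_te_table",
    "write_te_table",
]

ASSIGNABLE_LENGTHS = (28, 29, 30)

#: (read length, frame shift) -> nucleotide position of the A-site codon
#: within the read (1-based).  Shift is the offset of the read's first
#: nucleotide from the closest codon start: 0 in frame, +1 one before,
#: -1 one after.  Cells absent from the table are ambiguous and the read
#: is discarded.
_ASITE_NT = {
    (28, +1): 15,
    (28, 0): 16,
    (29, 0): 16,
    (30, 0): 16,
    (30, -1): 17,
}


@dataclass(frozen=True)
class ReadRecord:
    gene_id: str
    length_nt: int
    start_offset_nt: int  # 0-based offset of the first nucleotide in the ORF

    def __post_init__(self):
        if self.start_offset_nt < 0:
            raise ValueError("start offset must be non-negative")


@dataclass(frozen=True)
class TERecord:
    gene_id: str
    te: float
    density: float | None = None  # ribosomes per 100 codons, if measured

    def __post_init__(self):
        if self.te < 0:
            raise ValueError("TE must be non-negative")


def _frame_shift(start_offset_nt: int) -> int:
    """Recode offset mod 3 as {0, +1, -1} relative to the closest codon start."""
    m = start_offset_nt % 3
    return {0: 0, 1: 1, 2: -1}[m]


def asite_nt_position(length_nt: int, shift: int) -> int | None:
    """First nucleotide (1-based, within the read) of the A-site codon.

    This is the raw assignment rule: 15 for (28, +1), 16 for (28, 0),
    (29, 0) and (30, 0), 17 for (30, -1); every other (length, shift)
    cell is ambiguous and discarded.  Note each retained cell lands on a
    codon boundary of the ORF.
    """
    return _ASITE_NT.get((length_nt, shift))


def map_read(read: ReadRecord) -> int | None:
    """Assign a footprint read to its A-site codon, or None if discarded.

    Returns the 1-based codon index within the ORF.  Reads outside
    lengths 28-30 nt, or in a (length, shift) cell with ambiguous A-site
    position, are discarded.
    """
    if read.length_nt not in ASSIGNABLE_LENGTHS:
        return None
    shift = _frame_shift(read.start_offset_nt)
    asite_nt = _ASITE_NT.get((read.length_nt, shift))
    if asite_nt is None:
        return None
    # absolute 0-based nucleotide of the A-site codon's first position
    nt = read.start_offset_nt + (asite_nt - 1)
    return nt // 3 + 1


def filter_genes(
    profiles: dict[str, np.ndarray],
    min_len: int = 200,
    min_mean_reads: float = 10.0,
) -> list[str]:
    """Genes longer than ``min_len`` codons with mean per-codon count
    above ``min_mean_reads``."""
    kept = []
    for gene_id, counts in profiles.items():
        counts = np.asarray(counts)
        if counts.size > min_len and counts.mean() > min_mean_reads:
            kept.append(gene_id)
    return kept


@dataclass(frozen=True)
class TEScaling:
    """Result of the TE-vs-density calibration: TE = c * density."""

    c: float
    n_used: int
    residual_sd: float

    def density_from_te(self, te):
        """Detected-ribosome density (per 100 codons) implied by a TE."""
        return np.asarray(te, dtype=float) / self.c


def fit_te_scaling(
    records: list[TERecord] | pd.DataFrame,
    density_cutoff: float = 1.0,
) -> TEScaling:
    """Through-origin least squares of TE on density, low-density genes only.

    TE is proportional to the per-transcript detected-ribosome density;
    the proportionality constant is estimated on genes with measured
    density below ``density_cutoff`` ribosomes per 100 codons, where
    stacking (and hence undetected ribosomes) is negligible.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(
            [(r.gene_id, r.te, r.density) for r in records],
            columns=["gene_id", "te", "density"],
        )
    df = df.dropna(subset=["density"])
    low = df[df["density"] < density_cutoff]
    if len(low) < 2:
        raise ValueError(
            f"need >= 2 records with density < {density_cutoff}, "
            f"got {len(low)}"
        )
    d = low["density"].to_numpy(float)
    te = low["te"].to_numpy(float)
    c = float(np.dot(te, d) / np.dot(d, d))
    resid = te - c * d
    return TEScaling(
        c=c, n_used=len(low), residual_sd=float(np.std(resid, ddof=1))
    )


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

STOP_CODONS = {"TAA", "TAG", "TGA"}


def read_coding_fasta(path, require_start_stop: bool = True) -> dict[str, str]:
    """Coding sequences keyed by record id; validated as ORFs.

    Each sequence must have length divisible by 3; with
    ``require_start_stop`` it must begin with ATG and end with a stop
    codon.
    """
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        if len(s) % 3 != 0:
            raise ValueError(f"{rec.id}: length {len(s)} not divisible by 3")
        if require_start_stop:
            if not s.startswith("ATG"):
                raise ValueError(f"{rec.id}: does not start with ATG")
            if s[-3:] not in STOP_CODONS:
                raise ValueError(f"{rec.id}: does not end with a stop codon")
        seqs[rec.id] = s
    return seqs


def read_profiles(path) -> dict[str, np.ndarray]:
    """Footprint profiles from a TSV with columns gene_id, position, count."""
    df = pd.read_csv(path, sep="\t")
    profiles = {}
    for gene_id, sub in df.groupby("gene_id", sort=False):
        L = int(sub["position"].max())
        counts = np.zeros(L, dtype=np.int64)
        counts[sub["position"].to_numpy(int) - 1] = sub["count"].to_numpy(int)
        profiles[str(gene_id)] = counts
    return profiles


def write_profiles(profiles: dict[str, np.ndarray], path) -> None:
    frames = []
    for gene_id, counts in profiles.items():
        counts = np.asarray(counts)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_id,
                    "position": np.arange(1, counts.size + 1),
                    "count": counts,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_read_records(path) -> list[ReadRecord]:
    """Read records from a TSV with columns gene_id, length_nt,
    start_offset_nt."""
    df = pd.read_csv(path, sep="\t")
    return [
        ReadRecord(str(r.gene_id), int(r.length_nt), int(r.start_offset_nt))
        for r in df.itertuples(index=False)
    ]


def write_read_records(records: list[ReadRecord], path) -> None:
    pd.DataFrame(
        [(r.gene_id, r.length_nt, r.start_offset_nt) for r in records],
        columns=["gene_id", "length_nt", "start_offset_nt"],
    ).to_csv(path, sep="\t", index=False)


def reads_to_profiles(
    records: list[ReadRecord], lengths: dict[str, int]
) -> tuple[dict[str, np.ndarray], int]:
    """Accumulate A-site assignments into per-gene codon profiles.

    ``lengths`` gives each gene's length in codons; assignments falling
    outside a gene are discarded.  Returns the profiles and the number
    of discarded reads.
    """
    profiles = {g: np.zeros(L, dtype=np.int64) for g, L in lengths.items()}
    discarded = 0
    for r in records:
        codon = map_read(r)
        if (
            codon is None
            or r.gene_id not in profiles
            or codon > lengths[r.gene_id]
        ):
            discarded += 1
            continue
        profiles[r.gene_id][codon - 1] += 1
    return profiles, discarded


def read_te_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "density" not in df.columns:
        df["density"] = np.nan
    return df


def write_te_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
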