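"""Reading Ribo-seq inputs and producing normalized density profiles.

This module turns raw A-site-mappable footprint records or per-codon count
tables into the normalized experimental density profiles ``{r_i}`` (units of
ribosomes, i.e. A-sites, per codon) that the inference consumes:

1. footprint records (5' position, fragment length, reading frame) are mapped
   to A-site codons via the fragment-size/frame offset table used for yeast
   monosome footprints (27–33 nt);
2. per-gene, per-codon A-site counts are normalized by the gene's total count
   and put on an absolute scale with the gene's mean ribosome density from
   polysome profiling, so that ``mean(r_i)`` equals the supplied density;
3. genes with insufficient coverage (mean reads/codon below 10 by default) or
   with an unphysical normalized density (``r_i > 1``) are rejected with an
   explicit reason.

Primary interchange is TSV; a best-effort reader for Riboviz-style HDF5 count
tables is provided (layout documented on :func:`read_counts_hdf5`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model_core import DEFAULT_ELL

__all__ = [
    "ASITE_OFFSETS",
    "DISCARD",
    "FootprintRecord",
    "RawProfile",
    "NormalizedProfile",
    "GeneRejected",
    "FilterResult",
    "map_asite",
    "asite_offset",
    "aggregate_counts",
    "normalize",
    "filter_gene",
    "read_counts_tsv",
    "read_densities_tsv",
    "read_footprints_tsv",
    "read_counts_hdf5",
    "write_profiles_tsv",
    "read_profiles_tsv",
]

#: A-site offset (nt from the fragment 5' end to the first nt of the A-site
#: codon) by (fragment length, frame).  ``None`` marks ambiguous cells whose
#: reads are discarded.
ASITE_OFFSETS: dict[tuple[int, int], int | None] = {
    (27, 0): 15, (27, 1): 15, (27, 2): 18,
    (28, 0): 15, (28, 1): 15, (28, 2): 18,
    (29, 0): 15, (29, 1): None, (29, 2): 18,
    (30, 0): 15, (30, 1): 18, (30, 2): 18,
    (31, 0): 15, (31, 1): 18, (31, 2): 18,
    (32, 0): None, (32, 1): 18, (32, 2): 18,
    (33, 0): 18, (33, 1): 18, (33, 2): 18,
}

MIN_FOOTPRINT, MAX_FOOTPRINT = 27, 33


class _Discard:
    """Sentinel for footprint records that cannot be A-site assigned."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "DISCARD"


DISCARD = _Discard()


@dataclass(frozen=True)
class FootprintRecord:
    """One ribosome-protected fragment in CDS coordinates.

    ``five_prime_nt`` is the 0-based nucleotide position of the fragment's 5'
    end relative to the first nt of the START codon; ``frame`` is that
    position modulo 3 (computed if omitted).
    """

    gene_id: str
    five_prime_nt: int
    length: int
    frame: int | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("fragment length must be positive")
        if self.frame is None:
            object.__setattr__(self, "frame", self.five_prime_nt % 3)
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")


def asite_offset(length: int, frame: int) -> int | None:
    """Offset lookup by (fragment length, frame); ``None`` for discarded cells."""
    return ASITE_OFFSETS.get((length, frame))


def map_asite(record: FootprintRecord):
    """A-site codon index for a footprint record, or :data:`DISCARD`.

    The offset is a pure (length, frame) lookup; the A-site codon is
    ``floor((five_prime_nt + offset) / 3) + 1`` with codon 1 = START.
    Fragments outside 27..33 nt and ambiguous (length, frame) cells are
    discarded.
    """
    off = asite_offset(record.length, record.frame)
    if off is None:
        return DISCARD
    return (record.five_prime_nt + off) // 3 + 1


@dataclass
class RawProfile:
    """Per-codon A-site read counts ``c_i`` for codons ``2..L``."""

    gene_id: str
    counts: np.ndarray
    L: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (self.L - 1,):
            raise ValueError(f"counts must have length L-1={self.L - 1}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def codons(self) -> np.ndarray:
        return np.arange(2, self.L + 1)


@dataclass
class NormalizedProfile:
    """Normalized experimental densities ``r_i`` (A-sites per codon).

    ``sum(r_i) = N``, the mean number of ribosomes on the transcript, and
    ``mean(r_i)`` equals the absolute polysome-profiling density used for
    normalization.
    """

    gene_id: str
    r: np.ndarray
    ell: int = DEFAULT_ELL

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if np.any(self.r < 0):
            raise ValueError("r_i must be non-negative")
        if np.any(self.r > 1):
            raise GeneRejected(self.gene_id, "density>1")

    @property
    def L(self) -> int:
        return self.r.size + 1

    @property
    def r_mean(self) -> float:
        return float(self.r.mean())

    @property
    def N(self) -> float:
        """Mean ribosome count on the transcript, ``r_mean * (L - 1)``."""
        return float(self.r.sum())

    def codons(self) -> np.ndarray:
        return np.arange(2, self.L + 1)


class GeneRejected(Exception):
    """A gene cannot be normalized or analysed; carries a reason code."""

    def __init__(self, gene_id: str, reason: str):
        self.gene_id = gene_id
        self.reason = reason
        super().__init__(f"{gene_id}: {reason}")


def aggregate_counts(
    records: Iterable[FootprintRecord], gene_lengths: Mapping[str, int]
) -> tuple[dict[str, RawProfile], dict[str, int]]:
    """Histogram A-site codons per gene; count every discard by reason.

    ``gene_lengths`` maps gene_id to L (codons including START and STOP).
    Reason codes: ``length_out_of_range``, ``ambiguous_offset`` ('X' cells),
    ``unknown_gene``, ``start_codon`` (A-site on codon 1, discarded),
    ``outside_cds``.
    """
    counts = {
        g: np.zeros(L - 1, dtype=np.int64) for g, L in gene_lengths.items()
    }
    reasons = {
        "length_out_of_range": 0,
        "ambiguous_offset": 0,
        "unknown_gene": 0,
        "start_codon": 0,
        "outside_cds": 0,
    }
    for rec in records:
        if not (MIN_FOOTPRINT <= rec.length <= MAX_FOOTPRINT):
            reasons["length_out_of_range"] += 1
            continue
        codon = map_asite(rec)
        if codon is DISCARD:
            reasons["ambiguous_offset"] += 1
            continue
        if rec.gene_id not in counts:
            reasons["unknown_gene"] += 1
            continue
        L = gene_lengths[rec.gene_id]
        if codon == 1:
            reasons["start_codon"] += 1
        elif 2 <= codon <= L:
            counts[rec.gene_id][codon - 2] += 1
        else:
            reasons["outside_cds"] += 1
    profiles = {
        g: RawProfile(g, c, gene_lengths[g]) for g, c in counts.items()
    }
    return profiles, reasons


def normalize(
    raw: RawProfile, mean_density: float, ell: int = DEFAULT_ELL
) -> NormalizedProfile:
    """Scale a count profile to absolute densities via polysome profiling.

    ``r_i = (c_i / total) * N`` with ``N = mean_density * (L - 1)``, so the
    profile's mean density equals the supplied experimental value
    (ribosomes/codon).  Raises :class:`GeneRejected` with reason ``"no reads"``
    for an empty profile and ``"density>1"`` when any codon's normalized
    density exceeds one ribosome.
    """
    if raw.total == 0:
        raise GeneRejected(raw.gene_id, "no reads")
    if not mean_density > 0:
        raise ValueError("mean_density must be > 0")
    N = mean_density * (raw.L - 1)
    r = raw.counts / raw.total * N
    if np.any(r > 1):
        raise GeneRejected(raw.gene_id, "density>1")
    return NormalizedProfile(raw.gene_id, r, ell=ell)


@dataclass
class FilterResult:
    passed: bool
    reason: str | None
    mean_reads: float
    zero_count_codons: np.ndarray = field(default_factory=lambda: np.array([], int))


def filter_gene(raw: RawProfile, min_mean_reads: float = 10.0) -> FilterResult:
    """Coverage filter: pass iff mean reads/codon >= threshold (inclusive).

    Zero-count codons inside passing genes are reported — their density would
    imply an unboundedly fast codon and the inference flags them downstream.
    """
    mean_reads = raw.total / (raw.L - 1)
    zeros = raw.codons()[raw.counts == 0]
    if raw.total == 0:
        return FilterResult(False, "no reads", 0.0, zeros)
    if mean_reads < min_mean_reads:
        return FilterResult(False, "low coverage", mean_reads, zeros)
    return FilterResult(True, None, mean_reads, zeros)


# ---------------------------------------------------------------------------
# file formats (TSV primary; HDF5 read-only, best effort)

def read_counts_tsv(path) -> dict[str, RawProfile]:
    """Counts TSV with columns gene_id, codon, count (codons 2..L, L inferred
    from the largest codon present per gene; absent codons are zero)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for gene, sub in df.groupby("gene_id", sort=False):
        L = int(sub["codon"].max())
        counts = np.zeros(L - 1, dtype=np.int64)
        counts[sub["codon"].to_numpy() - 2] = sub["count"].to_numpy()
        out[str(gene)] = RawProfile(str(gene), counts, L)
    return out


def read_densities_tsv(path) -> dict[str, float]:
    """Polysome densities TSV with columns gene_id, density (ribosomes/codon)."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["gene_id"].astype(str), df["density"].astype(float)))


def read_footprints_tsv(path) -> list[FootprintRecord]:
    """Footprint records TSV with columns gene_id, pos5, length (frame derived)."""
    df = pd.read_csv(path, sep="\t")
    return [
        FootprintRecord(str(g), int(p), int(n))
        for g, p, n in zip(df["gene_id"], df["pos5"], df["length"])
    ]


def read_counts_hdf5(path, gene_lengths: Mapping[str, int]) -> dict[str, RawProfile]:
    """Best-effort reader for Riboviz-style HDF5 count tables.

    Expected layout: one group per gene containing a 2-D integer dataset
    ``reads`` of shape (n_lengths, n_positions) — rows indexed by fragment
    length given in the group attribute ``lengths``, columns by 0-based nt
    position of the fragment 5' end relative to the CDS start.  Each cell is
    expanded into footprint records and A-site mapped like TSV input.
    """
    import h5py

    records: list[FootprintRecord] = []
    with h5py.File(path, "r") as f:
        for gene in f:
            if gene not in gene_lengths:
                continue
            grp = f[gene]
            data = np.asarray(grp["reads"])
            lengths = np.asarray(grp.attrs["lengths"], dtype=int)
            for li, ln in enumerate(lengths):
                pos_counts = data[li]
                for pos in np.nonzero(pos_counts)[0]:
                    records.extend(
                        [FootprintRecord(gene, int(pos), int(ln))]
                        * int(pos_counts[pos])
                    )
    profiles, _ = aggregate_counts(records, gene_lengths)
    return profiles


def write_profiles_tsv(profiles: Iterable[NormalizedProfile], path) -> None:
    frames = [
        pd.DataFrame({"gene_id": p.gene_id, "codon": p.codons(), "r": p.r})
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path, ell: int = DEFAULT_ELL) -> dict[str, NormalizedProfile]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for gene, sub in df.groupby("gene_id", sort=False):
        sub = sub.sort_values("codon")
        out[str(gene)] = NormalizedProfile(
            str(gene), sub["r"].to_numpy(float), ell=ell
        )
    return out
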