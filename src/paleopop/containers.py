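"""Core in-memory containers shared across the package.

Genotype data are held as dense numpy dosage matrices (samples x sites) with
``-1`` as the missing sentinel, which keeps masking bit-exact and makes the
simulators, filters and likelihood code straightforward vector operations.
Sample metadata travels separately as a pandas DataFrame with columns
``sample_id``, ``population``, ``era``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: IUPAC nucleotide codes (upper case) plus gap; ambiguity codes are accepted
#: on input and treated as missing by the diversity statistics.
IUPAC_CHARS = frozenset("ACGTURYSWKMBDHVN-")


def make_labels(sample_ids: Sequence[str], population: Sequence[str] | str,
                era: Sequence[str] | str) -> pd.DataFrame:
    """Build a sample-metadata frame (sample_id, population, era)."""
    n = len(sample_ids)
    if isinstance(population, str):
        population = [population] * n
    if isinstance(era, str):
        era = [era] * n
    return pd.DataFrame(
        {"sample_id": list(sample_ids), "population": list(population),
         "era": list(era)}
    )


def _check_sites(sites: pd.DataFrame) -> None:
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(sites.columns):
        raise ValueError(f"site table needs columns {sorted(required)}")
    key = list(zip(sites["chrom"], sites["pos"]))
    if len(set(key)) != len(key):
        raise ValueError("duplicate (chrom, pos) in site table")
    for _, grp in sites.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError("positions must be sorted within chromosome")


@dataclass
class GenotypeMatrix:
    """Diploid biallelic dosage matrix.

    Attributes
    ----------
    samples : np.ndarray of str
        Unique sample identifiers, one per row of ``dosages``.
    sites : pd.DataFrame
        Columns ``chrom``, ``pos`` (1-based), ``ref``, ``alt``; one row per
        column of ``dosages``; (chrom, pos) unique and position-sorted.
    dosages : np.ndarray, int8
        Count of alternate alleles in {0, 1, 2}, or -1 for missing.
    ancestral_freq, pop_freqs
        Optional simulation provenance: the per-site ancestral alternate-allele
        frequency and the per-population frequencies the genotypes were drawn
        from. ``None`` for data read from files.
    """

    samples: np.ndarray
    sites: pd.DataFrame
    dosages: np.ndarray
    ancestral_freq: np.ndarray | None = None
    pop_freqs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or -1 (missing)")
        _check_sites(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def dosages_float(self) -> np.ndarray:
        """Dosages as float with missing as NaN."""
        out = self.dosages.astype(float)
        out[self.dosages == MISSING] = np.nan
        return out

    def sample_index(self, sample_id: str) -> int:
        idx = np.flatnonzero(self.samples == sample_id)
        if idx.size != 1:
            raise KeyError(f"sample {sample_id!r} not in matrix")
        return int(idx[0])

    def subset(self, sample_idx: Iterable[int] | None = None,
               site_idx: Iterable[int] | None = None) -> "GenotypeMatrix":
        """Row/column subset; indices are positional and order-preserving."""
        si = (np.arange(self.n_samples) if sample_idx is None
              else np.asarray(list(sample_idx), dtype=np.intp))
        vi = (np.arange(self.n_sites) if site_idx is None
              else np.asarray(list(site_idx), dtype=np.intp))
        return GenotypeMatrix(
            samples=self.samples[si],
            sites=self.sites.iloc[vi].reset_index(drop=True),
            dosages=self.dosages[np.ix_(si, vi)],
            ancestral_freq=None if self.ancestral_freq is None else self.ancestral_freq[vi],
            pop_freqs=None if self.pop_freqs is None else self.pop_freqs.iloc[vi].reset_index(drop=True),
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        return self.subset(sample_idx=[self.sample_index(s) for s in sample_ids])


@dataclass
class PseudohaploidCalls:
    """Single sampled allele per sample x site: 0 (ref), 1 (alt), -1 missing.

    The standard representation for low-coverage ancient samples, where one
    read-backed allele is drawn per site and heterozygosity is unobservable.
    """

    samples: np.ndarray
    sites: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError("calls shape does not match samples x sites")
        if ~np.isin(self.calls, (0, 1, MISSING)).all():
            raise ValueError("pseudohaploid calls must be 0, 1 or -1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def n_called(self) -> np.ndarray:
        """Number of genotyped sites per sample."""
        return (self.calls != MISSING).sum(axis=1)

    def sample_index(self, sample_id: str) -> int:
        idx = np.flatnonzero(self.samples == sample_id)
        if idx.size != 1:
            raise KeyError(f"sample {sample_id!r} not in calls")
        return int(idx[0])

    def to_dosage_matrix(self) -> GenotypeMatrix:
        """Represent calls as homozygous dosages {0, 2} (for VCF export)."""
        d = np.where(self.calls == MISSING, MISSING, self.calls * 2).astype(np.int8)
        return GenotypeMatrix(samples=self.samples.copy(), sites=self.sites,
                              dosages=d)

    @classmethod
    def from_dosage_matrix(cls, matrix: GenotypeMatrix) -> "PseudohaploidCalls":
        """Interpret a {0, 2}-only dosage matrix as pseudohaploid calls."""
        if (matrix.dosages == 1).any():
            raise ValueError("heterozygous dosages cannot be pseudohaploid")
        calls = np.where(matrix.dosages == MISSING, MISSING,
                         matrix.dosages // 2).astype(np.int8)
        return cls(samples=matrix.samples.copy(), sites=matrix.sites, calls=calls)


@dataclass
class HaplotypeAlignment:
    """Gap-aware aligned haplotype sequences with group labels.

    ``seqs`` is an (n, L) byte matrix (dtype ``S1``, upper case). ``in_clade``
    optionally flags membership of a designated clade (e.g. the historic
    clade that contains all archaeological samples); the clade is an input,
    not inferred.
    """

    ids: np.ndarray
    seqs: np.ndarray
    groups: np.ndarray | None = None
    eras: np.ndarray | None = None
    in_clade: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.seqs = np.asarray(self.seqs, dtype="S1")
        if self.seqs.ndim != 2 or self.seqs.shape[0] != len(self.ids):
            raise ValueError("seqs must be an (n_sequences, length) matrix")
        chars = {c.decode() for c in np.unique(self.seqs)}
        bad = chars - IUPAC_CHARS
        if bad:
            raise ValueError(f"non-IUPAC characters in alignment: {sorted(bad)}")
        for name, arr in (("groups", self.groups), ("eras", self.eras),
                          ("in_clade", self.in_clade)):
            if arr is not None and len(arr) != len(self.ids):
                raise ValueError(f"{name} length does not match ids")
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=object)
        if self.eras is not None:
            self.eras = np.asarray(self.eras, dtype=object)
        if self.in_clade is not None:
            self.in_clade = np.asarray(self.in_clade, dtype=bool)

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return self.seqs.shape[1]

    def sequence(self, i: int) -> str:
        return self.seqs[i].tobytes().decode()

    def mask(self, keep: np.ndarray) -> "HaplotypeAlignment":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return HaplotypeAlignment(
            ids=self.ids[keep],
            seqs=self.seqs[keep],
            groups=None if self.groups is None else self.groups[keep],
            eras=None if self.eras is None else self.eras[keep],
            in_clade=None if self.in_clade is None else self.in_clade[keep],
        )

    def group_mask(self, group: str) -> np.ndarray:
        if self.groups is None:
            raise ValueError("alignment carries no group labels")
        return self.groups == group


__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PseudohaploidCalls",
    "HaplotypeAlignment",
    "make_labels",
]
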