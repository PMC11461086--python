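"""Reading/writing the panel formats and the variant/sample filters.

VCF handling targets the minimal dialect the rest of the package needs:
v4.2, biallelic SNPs, a GT-only FORMAT, ``./.`` for missing. Reading goes
through pysam (so anything htslib accepts is fine); writing is a small
deterministic text writer so that pipeline outputs are byte-reproducible.

The filters mirror the conventional PLINK-style pre-processing of a variant
panel: site call-rate and minor-allele-frequency thresholds, a sample
missingness tolerance, and windowed variance-inflation-factor (VIF) pruning
of linked variants (PLINK ``indep`` semantics, e.g. "50 5 2").
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from paleopop.containers import (
    MISSING,
    GenotypeMatrix,
    HaplotypeAlignment,
)


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted as a biallelic diploid GT."""


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write the matrix as minimal VCF v4.2 (GT only, ``./.`` for missing)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=paleopop\n")
        for chrom in pd.unique(matrix.sites["chrom"]):
            length = int(matrix.sites.loc[matrix.sites["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={length + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in matrix.samples) + "\n")
        sites = matrix.sites
        dosages = matrix.dosages
        for j in range(matrix.n_sites):
            row = sites.iloc[j]
            gts = "\t".join(_GT_STRING[int(d)] for d in dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path, skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix.

    Multiallelic records are skipped (with a warning) or rejected depending on
    ``skip_multiallelic``. Non-diploid GT fields raise :class:`VcfParseError`
    naming the record.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        chroms, poss, refs, alts = [], [], [], []
        columns = []
        n_skipped = 0
        for rec_no, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            alleles = rec.alts or ()
            if len(alleles) != 1:
                if skip_multiallelic:
                    n_skipped += 1
                    continue
                raise VcfParseError(
                    f"record {rec_no} ({rec.chrom}:{rec.pos}): not biallelic"
                )
            col = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or all(a is None for a in gt):
                    col[i] = MISSING
                    continue
                if len(gt) != 2 or any(a is None for a in gt):
                    raise VcfParseError(
                        f"record {rec_no} ({rec.chrom}:{rec.pos}), sample {s}: "
                        f"non-diploid GT {gt!r}"
                    )
                if not all(a in (0, 1) for a in gt):
                    raise VcfParseError(
                        f"record {rec_no} ({rec.chrom}:{rec.pos}), sample {s}: "
                        f"allele index out of range in GT {gt!r}"
                    )
                col[i] = gt[0] + gt[1]
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            refs.append(rec.ref)
            alts.append(alleles[0])
            columns.append(col)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multiallelic records")
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosages = (np.stack(columns, axis=1) if columns
               else np.empty((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples=np.array(samples, dtype=object),
                          sites=sites, dosages=dosages)


def site_stats(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-site MAF, call rate, alt-allele count and called-sample count.

    MAF is computed over called genotypes only: ``min(f, 1-f)`` of the
    alternate-allele frequency among non-missing samples.
    """
    d = matrix.dosages
    called = d != MISSING
    n_called = called.sum(axis=0)
    alt_count = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt_count / (2.0 * n_called), np.nan)
    maf = np.where(np.isnan(freq), np.nan, np.minimum(freq, 1.0 - freq))
    call_rate = n_called / matrix.n_samples if matrix.n_samples else n_called * 0.0
    return pd.DataFrame({"maf": maf, "call_rate": call_rate,
                         "alt_count": alt_count, "n_called": n_called})


def filter_sites(matrix: GenotypeMatrix, min_call_rate: float = 0.5,
                 min_maf: float = 0.05) -> GenotypeMatrix:
    """Keep sites with call rate >= min_call_rate and MAF >= min_maf.

    Boundary values are retained; site order is preserved. Idempotent.
    """
    if not (0.0 <= min_call_rate <= 1.0 and 0.0 <= min_maf <= 1.0):
        raise ValueError("thresholds must be in [0, 1]")
    stats = site_stats(matrix)
    keep = ((stats["call_rate"].to_numpy() >= min_call_rate)
            & (np.nan_to_num(stats["maf"].to_numpy(), nan=-1.0) >= min_maf))
    if not keep.any():
        warnings.warn("site filter removed every site")
    return matrix.subset(site_idx=np.flatnonzero(keep))


def filter_samples(matrix: GenotypeMatrix,
                   max_missing: float = 0.9) -> GenotypeMatrix:
    """Keep samples whose missing-site fraction is <= max_missing."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    if matrix.n_sites == 0:
        return matrix
    miss = (matrix.dosages == MISSING).mean(axis=1)
    return matrix.subset(sample_idx=np.flatnonzero(miss <= max_missing))


def _mean_imputed(matrix: GenotypeMatrix) -> np.ndarray:
    d = matrix.dosages_float()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        means = np.nanmean(d, axis=0)
    means = np.nan_to_num(means, nan=0.0)
    idx = np.where(np.isnan(d))
    d[idx] = means[idx[1]]
    return d


def _vif(y: np.ndarray, X: np.ndarray, ridge: float) -> float:
    """VIF = 1/(1-R^2) of y regressed on the columns of X (with intercept)."""
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst <= 0.0:
        return 1.0  # constant column: no inflation measurable
    Xc = X - X.mean(axis=0)
    gram = Xc.T @ Xc + ridge * np.eye(Xc.shape[1])
    beta = np.linalg.solve(gram, Xc.T @ yc)
    resid = yc - Xc @ beta
    r2 = 1.0 - float(resid @ resid) / sst
    if r2 >= 1.0:
        return np.inf
    return 1.0 / (1.0 - r2)


def ld_prune(matrix: GenotypeMatrix, window: int = 50, step: int = 5,
             vif_threshold: float = 2.0, ridge: float = 1e-8) -> np.ndarray:
    """Windowed greedy VIF pruning; returns the retained site indices.

    Within each window of ``window`` variants (advanced by ``step``), variants
    are scanned left to right and removed when their variance-inflation factor
    against the other still-retained variants in the window exceeds
    ``vif_threshold``. Dosages are mean-imputed; a small ridge term guards
    singular regressions. Deterministic given input order, and stable:
    re-pruning the output removes nothing.
    """
    if not window > step >= 1:
        raise ValueError("require window > step >= 1")
    d = _mean_imputed(matrix)
    n_sites = matrix.n_sites
    kept = np.ones(n_sites, dtype=bool)
    start = 0
    while True:
        stop = min(start + window, n_sites)
        for j in range(start, stop):
            if not kept[j]:
                continue
            others = [k for k in range(start, stop) if kept[k] and k != j]
            if not others:
                continue
            if _vif(d[:, j], d[:, others], ridge) > vif_threshold:
                kept[j] = False
        if stop >= n_sites:
            break
        start += step
    return np.flatnonzero(kept)


# ---------------------------------------------------------------------------
# FASTA alignments


def _parse_header(description: str):
    fields = description.split("|")
    sid = fields[0].strip()
    group = fields[1].strip() if len(fields) > 1 and fields[1].strip() else None
    era = fields[2].strip() if len(fields) > 2 and fields[2].strip() else None
    clade = None
    if len(fields) > 3:
        clade = fields[3].strip().lower() in ("clade", "historic", "1", "true")
    return sid, group, era, clade


def read_fasta_alignment(path) -> HaplotypeAlignment:
    """Read an aligned FASTA; headers may encode ``id|group|era[|clade]``.

    Sequences are upper-cased; ragged input is rejected naming the offending
    sequence.
    """
    ids, groups, eras, clades, rows = [], [], [], [], []
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        sid, group, era, clade = _parse_header(rec.description)
        seq = str(rec.seq).upper()
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"ragged alignment: sequence {sid!r} has length {len(seq)}, "
                f"expected {length}"
            )
        ids.append(sid)
        groups.append(group)
        eras.append(era)
        clades.append(clade)
        rows.append(np.frombuffer(seq.encode(), dtype="S1"))
    if not rows:
        raise ValueError(f"no sequences in {path}")
    any_meta = any(g is not None for g in groups)
    any_clade = any(c is not None for c in clades)
    return HaplotypeAlignment(
        ids=np.array(ids, dtype=object),
        seqs=np.vstack(rows),
        groups=np.array(groups, dtype=object) if any_meta else None,
        eras=np.array(eras, dtype=object) if any(e is not None for e in eras) else None,
        in_clade=np.array([bool(c) for c in clades]) if any_clade else None,
    )


def write_fasta_alignment(alignment: HaplotypeAlignment, path) -> None:
    """Write FASTA with ``id|group|era[|clade]`` headers (when labelled)."""
    records = []
    for i in range(alignment.n_sequences):
        parts = [str(alignment.ids[i])]
        if alignment.groups is not None:
            parts.append(str(alignment.groups[i]))
            parts.append(str(alignment.eras[i]) if alignment.eras is not None else "")
            if alignment.in_clade is not None:
                parts.append("clade" if alignment.in_clade[i] else ".")
        name = "|".join(parts)
        records.append(SeqRecord(Seq(alignment.sequence(i)), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


__all__ = [
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "site_stats",
    "filter_sites",
    "filter_samples",
    "ld_prune",
    "read_fasta_alignment",
    "write_fasta_alignment",
]
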