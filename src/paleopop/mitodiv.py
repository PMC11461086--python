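"""Mitogenome-alignment diversity statistics and resampling tests.

Statistics are the classical alignment summaries: nucleotide diversity (π,
mean pairwise differences per used site), Watterson's θ (from the count of
segregating sites, ``S / (a_{n-1} L)`` with ``a_k = sum_{i<=k} 1/i``), and
haplotype diversity with the ``n/(n-1)`` small-sample correction. Columns
containing a gap, N or any ambiguity code in an analysed sequence are
excluded ("complete deletion", the convention of the classical diversity
software); per-pair ("pairwise") deletion is available by flag for π.

The resampling machinery implements three study designs:

- repeated subsampling of modern clade members to compare their π against
  the archaeological members of the same clade (one-sample t-test);
- a label-permutation test for between-group differences in haplotype and
  nucleotide diversity;
- the clade-restriction test — the probability that all focal (ancient)
  tips fall inside a designated clade under random placement — reported both
  as the exact hypergeometric tail and as a permutation estimate with the
  (successes + 1)/(replicates + 1) correction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from paleopop.containers import HaplotypeAlignment

_ACGT = tuple(b"ACGT")


@dataclass
class DiversityStats:
    n: int
    S: int
    pi: float
    theta_w: float
    hap_div: float
    n_sites_used: int


def _select(alignment: HaplotypeAlignment, group=None, mask=None) -> np.ndarray:
    if mask is not None:
        mask = np.asarray(mask)
        if mask.dtype == bool:
            mask = np.flatnonzero(mask)
        return mask
    if group is not None:
        return np.flatnonzero(alignment.group_mask(group))
    return np.arange(alignment.n_sequences)


def _valid_columns(seqs: np.ndarray) -> np.ndarray:
    """Columns where every analysed sequence is unambiguous A/C/G/T."""
    u8 = seqs.view(np.uint8)
    valid = np.zeros(seqs.shape[1], dtype=int)
    for b in _ACGT:
        valid += (u8 == b).sum(axis=0)
    return valid == seqs.shape[0]


def harmonic(k: int) -> float:
    """a_k = sum_{i=1..k} 1/i, the Watterson denominator."""
    return float(np.sum(1.0 / np.arange(1, k + 1)))


def diversity(alignment: HaplotypeAlignment, group: str | None = None,
              mask=None, deletion: str = "complete") -> DiversityStats:
    """Diversity statistics of one group of sequences.

    π, Watterson's θ (both per used site) and haplotype diversity over exact
    full-length haplotype identity on the used columns. Groups of fewer than
    2 sequences are rejected.
    """
    idx = _select(alignment, group=group, mask=mask)
    n = len(idx)
    if n < 2:
        raise ValueError("diversity needs at least 2 sequences")
    seqs = alignment.seqs[idx]
    used = _valid_columns(seqs)
    L = int(used.sum())
    sub = seqs[:, used]
    u8 = sub.view(np.uint8)

    counts = np.stack([(u8 == b).sum(axis=0) for b in _ACGT])
    seg = (counts > 0).sum(axis=0) > 1
    S = int(seg.sum())

    n_pairs = n * (n - 1) / 2.0
    same_pairs = (counts * (counts - 1) / 2.0).sum(axis=0)
    total_diffs = float((n_pairs - same_pairs).sum())
    if deletion == "pairwise":
        # per-pair deletion, pooled as a ratio of sums:
        # sum(differences) / sum(compared columns) over all pairs
        u8_all = seqs.view(np.uint8)
        ok = np.zeros(seqs.shape, dtype=bool)
        for b in _ACGT:
            ok |= u8_all == b
        diffs, sites = 0.0, 0.0
        for i in range(n):
            for j in range(i + 1, n):
                both = ok[i] & ok[j]
                diffs += float((u8_all[i, both] != u8_all[j, both]).sum())
                sites += float(both.sum())
        pi = diffs / sites if sites else 0.0
    elif deletion == "complete":
        pi = total_diffs / (n_pairs * L) if L else 0.0
    else:
        raise ValueError("deletion must be 'complete' or 'pairwise'")

    theta_w = S / (harmonic(n - 1) * L) if L else 0.0

    hap_counts = np.fromiter(
        Counter(sub[i].tobytes() for i in range(n)).values(), dtype=float)
    p = hap_counts / n
    hap_div = n / (n - 1.0) * (1.0 - float((p**2).sum()))

    return DiversityStats(n=n, S=S, pi=float(pi), theta_w=float(theta_w),
                          hap_div=float(hap_div), n_sites_used=L)


@dataclass
class CladeResampleResult:
    """Modern-subset π values vs the ancient π within a clade."""

    resampled_pi: np.ndarray
    ancient_pi: float
    t: float
    p: float
    degenerate: bool
    k: int
    reps: int


def resample_clade_diversity(alignment: HaplotypeAlignment, k: int = 6,
                             reps: int = 10, seed=None,
                             restrict_groups=None) -> CladeResampleResult:
    """Repeatedly sample k modern clade members and compare π to the ancients.

    The clade membership flag on the alignment defines the clade; ancient π
    is computed from the flagged ancient tips. The one-sample t-test treats
    the resampled π values as the sample and the ancient π as the reference
    constant. When the resampled values have zero spread the test is
    degenerate and flagged (exhaustive subset, or duplicated haplotypes).
    """
    if alignment.in_clade is None or alignment.eras is None:
        raise ValueError("alignment needs clade flags and era labels")
    rng = np.random.default_rng(seed)
    modern = np.flatnonzero(alignment.in_clade & (alignment.eras == "modern"))
    if restrict_groups is not None:
        keep = np.isin(alignment.groups[modern], list(restrict_groups))
        modern = modern[keep]
    ancient = np.flatnonzero(alignment.in_clade & (alignment.eras == "ancient"))
    if len(modern) < k:
        raise ValueError(f"clade has only {len(modern)} modern members, need {k}")
    ancient_pi = diversity(alignment, mask=ancient).pi
    pis = np.empty(reps)
    for r in range(reps):
        pick = rng.choice(modern, size=k, replace=False)
        pis[r] = diversity(alignment, mask=pick).pi
    if np.ptp(pis) == 0.0:
        if pis[0] == ancient_pi:
            t, p, degenerate = 0.0, 1.0, False
        else:
            t, p, degenerate = np.nan, np.nan, True
    else:
        res = stats.ttest_1samp(pis, ancient_pi)
        t, p, degenerate = float(res.statistic), float(res.pvalue), False
    return CladeResampleResult(resampled_pi=pis, ancient_pi=float(ancient_pi),
                               t=t, p=p, degenerate=degenerate, k=k, reps=reps)


@dataclass
class DiversityPermutationResult:
    """Permutation p-values for between-group diversity differences."""

    observed_dhap: float
    observed_dpi: float
    p_hap: float
    p_pi: float
    reps: int


def diversity_permutation_test(alignment: HaplotypeAlignment, group_a: str,
                               group_b: str, reps: int = 100,
                               seed=None) -> DiversityPermutationResult:
    """Permutation test for |Δ haplotype diversity| and |Δ π| between groups.

    Labels are shuffled between the two groups holding sizes fixed;
    ``p = (#{permuted |Δ| >= observed |Δ|} + 1) / (reps + 1)``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    ia = np.flatnonzero(alignment.group_mask(group_a))
    ib = np.flatnonzero(alignment.group_mask(group_b))
    sa = diversity(alignment, mask=ia)
    sb = diversity(alignment, mask=ib)
    obs_dhap = abs(sa.hap_div - sb.hap_div)
    obs_dpi = abs(sa.pi - sb.pi)
    combined = np.concatenate([ia, ib])
    na = len(ia)
    hits_hap = hits_pi = 0
    eps = 1e-12  # float-noise guard so exact ties count as >= observed
    for _ in range(reps):
        perm = rng.permutation(combined)
        da = diversity(alignment, mask=perm[:na])
        db = diversity(alignment, mask=perm[na:])
        if abs(da.hap_div - db.hap_div) >= obs_dhap - eps:
            hits_hap += 1
        if abs(da.pi - db.pi) >= obs_dpi - eps:
            hits_pi += 1
    return DiversityPermutationResult(
        observed_dhap=float(obs_dhap), observed_dpi=float(obs_dpi),
        p_hap=(hits_hap + 1.0) / (reps + 1.0),
        p_pi=(hits_pi + 1.0) / (reps + 1.0), reps=reps,
    )


@dataclass
class CladeTestResult:
    """Exact and permutation probabilities of the clade-restriction pattern."""

    p_exact: float
    p_perm: float | None
    n_total: int
    n_clade: int
    n_focal: int
    n_focal_in_clade: int
    n_permutations: int
    seed: int | None


def clade_restriction_test(n_total: int, n_clade: int, n_focal: int,
                           n_focal_in_clade: int, n_permutations: int = 0,
                           seed=None, chunk: int = 100_000) -> CladeTestResult:
    """Probability that >= the observed number of focal tips fall in a clade.

    Under exchangeable random placement of the ``n_focal`` focal labels among
    ``n_total`` tips, the count inside a fixed ``n_clade``-tip clade is
    hypergeometric; ``p_exact`` is its upper tail at the observed count.
    ``p_perm`` re-places the focal labels uniformly ``n_permutations`` times
    and applies the (successes + 1)/(reps + 1) correction, converging to the
    exact tail as replicates grow.
    """
    if not (0 <= n_focal_in_clade <= min(n_focal, n_clade) <= n_total
            and n_focal <= n_total):
        raise ValueError("impossible clade-test counts")
    p_exact = float(stats.hypergeom.sf(n_focal_in_clade - 1, n_total,
                                       n_clade, n_focal))
    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        successes = 0
        remaining = n_permutations
        while remaining > 0:
            m = min(chunk, remaining)
            keys = rng.random((m, n_total))
            focal_pos = np.argpartition(keys, n_focal - 1, axis=1)[:, :n_focal]
            in_clade = (focal_pos < n_clade).sum(axis=1)
            successes += int((in_clade >= n_focal_in_clade).sum())
            remaining -= m
        p_perm = (successes + 1.0) / (n_permutations + 1.0)
    return CladeTestResult(p_exact=p_exact, p_perm=p_perm, n_total=n_total,
                           n_clade=n_clade, n_focal=n_focal,
                           n_focal_in_clade=n_focal_in_clade,
                           n_permutations=n_permutations,
                           seed=seed if isinstance(seed, int) else None)


def clade_census(alignment: HaplotypeAlignment):
    """(n_total, n_clade, n_focal, n_focal_in_clade) from alignment flags.

    Focal tips are the ancient-era sequences; the clade is the flagged one.
    """
    if alignment.in_clade is None or alignment.eras is None:
        raise ValueError("alignment needs clade flags and era labels")
    focal = alignment.eras == "ancient"
    return (alignment.n_sequences, int(alignment.in_clade.sum()),
            int(focal.sum()), int((focal & alignment.in_clade).sum()))


def percent_decline(start: float, end: float, ndigits: int = 0) -> float:
    """Percentage decline from ``start`` to ``end``: 100 (1 - end/start)."""
    if start <= 0:
        raise ValueError("start must be positive")
    return round(100.0 * (1.0 - end / start), ndigits)


__all__ = [
    "DiversityStats",
    "diversity",
    "harmonic",
    "CladeResampleResult",
    "resample_clade_diversity",
    "DiversityPermutationResult",
    "diversity_permutation_test",
    "CladeTestResult",
    "clade_restriction_test",
    "clade_census",
    "percent_decline",
]
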