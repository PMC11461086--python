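"""Pseudohaploid likelihood assignment with downsampling replicates.

The framework scores a pseudohaploid sample against a population's
alternate-allele frequencies: each called allele contributes ``ln f`` (alt)
or ``ln(1-f)`` (ref), and the sum is normalized to a per-site mean so that
values are comparable across variant sets of different size. Frequencies are
additively smoothed (pseudocount 0.5 per allele, Jeffreys-style) so unseen
alleles never produce -inf.

To compare data-rich modern samples with fragmentary ancient ones, every
sample is summarized by repeated downsampling to a fixed number of sites
(200 by default; 100 draws for the main variant set, 50 for each
sample-optimized set). A target's mean draw is then placed on the reference
distribution formed by the per-sample mean normalized lnL of each modern
population member (scored with leave-one-out frequencies), via a Z-test —
either against the reference mean or against its empirical 10% quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from paleopop.containers import MISSING, GenotypeMatrix, PseudohaploidCalls
from paleopop.simdata import pseudohaploidize


@dataclass
class PopFrequencies:
    """Smoothed per-population alternate-allele frequencies.

    ``freq`` is (n_populations, n_sites), strictly inside (0, 1) after
    additive smoothing; ``n_called_alleles`` counts the called alleles behind
    each estimate (0 means the smoothed frequency is a flat 0.5 placeholder,
    flagged by ``informative``).
    """

    populations: list[str]
    sites: pd.DataFrame
    freq: np.ndarray
    n_called_alleles: np.ndarray
    smoothing: float

    def row(self, population: str) -> np.ndarray:
        return self.freq[self.populations.index(population)]

    def informative(self, population: str) -> np.ndarray:
        return self.n_called_alleles[self.populations.index(population)] > 0


def pop_allele_frequencies(panel: GenotypeMatrix, labels: pd.DataFrame,
                           populations=None, smoothing: float = 0.5,
                           leave_out: str | None = None) -> PopFrequencies:
    """Per-population smoothed alternate-allele frequencies.

    ``freq = (alt_count + s) / (called_alleles + 2 s)`` with counts over
    called genotypes only. ``leave_out`` excludes one focal sample (for
    scoring a modern sample against its own population without
    self-inclusion bias). A site with zero called alleles in a population
    gets frequency exactly 0.5 with a zero-weight flag.
    """
    if smoothing <= 0:
        raise ValueError("smoothing pseudocount must be positive")
    if populations is None:
        populations = sorted(labels["population"].unique())
    freq = np.empty((len(populations), panel.n_sites))
    counts = np.empty((len(populations), panel.n_sites), dtype=np.int64)
    for k, pop in enumerate(populations):
        ids = [s for s in labels.loc[labels["population"] == pop, "sample_id"]
               if s != leave_out]
        if not ids:
            raise ValueError(f"population {pop!r} has no samples left")
        d = panel.dosages[[panel.sample_index(s) for s in ids]]
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0)
        alleles = 2 * called.sum(axis=0)
        freq[k] = (alt + smoothing) / (alleles + 2.0 * smoothing)
        counts[k] = alleles
    return PopFrequencies(populations=list(populations), sites=panel.sites,
                          freq=freq, n_called_alleles=counts,
                          smoothing=smoothing)


def sample_optimized_variant_set(target: PseudohaploidCalls, sample_id: str,
                                 panel: GenotypeMatrix,
                                 min_maf: float = 0.1,
                                 max_missing: float = 0.1) -> np.ndarray:
    """Sites genotyped in the focal sample that pass panel-level filters.

    The panel should already be restricted to the modern reference samples
    of interest (e.g. the two seasonal populations of one river). Filters are
    the study's assignment thresholds: panel MAF >= ``min_maf`` and panel
    missingness <= ``max_missing``. Deterministic; returns site indices.
    """
    from paleopop.popio import site_stats

    if len(target.sites) != panel.n_sites:
        raise ValueError("target and panel must share the same site table")
    i = target.sample_index(sample_id)
    called = target.calls[i] != MISSING
    stats_ = site_stats(panel)
    ok = (called
          & (np.nan_to_num(stats_["maf"].to_numpy(), nan=-1.0) >= min_maf)
          & (stats_["call_rate"].to_numpy() >= 1.0 - max_missing))
    if not ok.any():
        warnings.warn(f"no usable sites for sample {sample_id}")
    return np.flatnonzero(ok)


@dataclass
class LoglikResult:
    """Sum and per-site-normalized log likelihood of one sample vs one pop."""

    sum_lnl: float
    normalized: float
    n_used: int
    n_skipped: int


def sample_loglik(calls_row: np.ndarray, freqs: PopFrequencies,
                  population: str, sites: np.ndarray) -> LoglikResult:
    """Normalized log likelihood of a pseudohaploid sample given a population.

    Per-site contribution is ``ln f`` when the called allele is the alternate
    and ``ln(1-f)`` when it is the reference; the normalized value is the
    per-site mean (strictly <= 0 when any frequency < 1). Sites where the
    sample is not called, or where the population frequency is uninformative,
    are skipped and counted.
    """
    sites = np.asarray(sites)
    calls = np.asarray(calls_row)
    f = freqs.row(population)
    usable = (calls[sites] != MISSING) & freqs.informative(population)[sites]
    use = sites[usable]
    if use.size == 0:
        raise ValueError("zero usable sites: cannot compute a likelihood")
    contrib = np.where(calls[use] == 1, np.log(f[use]), np.log1p(-f[use]))
    total = float(contrib.sum())
    return LoglikResult(sum_lnl=total, normalized=total / use.size,
                        n_used=int(use.size),
                        n_skipped=int(sites.size - use.size))


@dataclass
class LnLDistribution:
    """Normalized lnL values from downsampling replicates of one sample."""

    sample_id: str
    population: str
    draws: np.ndarray
    n_sites_per_draw: int
    n_draws: int
    seed: int | None

    def mean(self) -> float:
        return float(self.draws.mean())


def downsample_loglik(calls_row: np.ndarray, freqs: PopFrequencies,
                      population: str, sites: np.ndarray,
                      n_sites_per_draw: int = 200, n_draws: int = 50,
                      rng: np.random.Generator | int | None = None,
                      sample_id: str = "") -> LnLDistribution:
    """Downsampling-bootstrap distribution of normalized log likelihoods.

    Each draw picks ``n_sites_per_draw`` sites uniformly without replacement
    from the usable sites (called in the sample, informative frequency) and
    records the per-site mean lnL; draws are independent. Refuses when fewer
    usable sites than the draw size exist.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sites = np.asarray(sites)
    calls = np.asarray(calls_row)
    usable = sites[(calls[sites] != MISSING)
                   & freqs.informative(population)[sites]]
    if usable.size < n_sites_per_draw:
        raise ValueError(
            f"only {usable.size} usable sites; cannot draw "
            f"{n_sites_per_draw} without replacement"
        )
    f = freqs.row(population)
    contrib = np.where(calls[usable] == 1, np.log(f[usable]),
                       np.log1p(-f[usable]))
    draws = np.empty(n_draws)
    for d in range(n_draws):
        # sorted picks make the summation order canonical, so an exhaustive
        # draw is bit-identical across replicates
        pick = np.sort(rng.choice(usable.size, size=n_sites_per_draw,
                                  replace=False))
        draws[d] = contrib[pick].mean()
    return LnLDistribution(sample_id=sample_id, population=population,
                           draws=draws, n_sites_per_draw=n_sites_per_draw,
                           n_draws=n_draws, seed=seed)


def reference_distribution(panel: GenotypeMatrix, labels: pd.DataFrame,
                           population: str, sites: np.ndarray | None = None,
                           n_sites_per_draw: int = 200, n_draws: int = 50,
                           smoothing: float = 0.5,
                           rng: np.random.Generator | int | None = None,
                           filter_panel: GenotypeMatrix | None = None,
                           target_called: np.ndarray | None = None,
                           min_maf: float = 0.1,
                           max_missing: float = 0.1) -> np.ndarray:
    """Per-member mean normalized lnL of each modern member vs its population.

    Every member is pseudohaploidized (one random allele per site), scored
    against leave-one-out smoothed frequencies of its own population, and
    summarized by the mean of its downsampling draws. The returned vector is
    the reference against which a target's mean draw is Z-tested.

    Leave-one-out is applied consistently: when ``filter_panel`` and
    ``target_called`` are given, each member's variant set is the
    sample-optimized set recomputed with that member excluded from the
    panel's MAF/missingness statistics. Without it, every member is scored
    on the fixed ``sites`` — which leaves a self-inclusion bias, because
    sites passing a frequency filter that the member's own genotypes helped
    satisfy are enriched for the member's minor alleles, depressing member
    scores relative to an outside target.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    members = list(labels.loc[labels["population"] == population, "sample_id"])
    if len(members) < 3:
        raise ValueError("reference distribution needs at least 3 members")
    loo_filter = filter_panel is not None and target_called is not None
    if not loo_filter and sites is None:
        raise ValueError("need either fixed sites or filter_panel + target_called")

    d_full = panel.dosages[[panel.sample_index(s) for s in members]]
    called_full = d_full != MISSING
    alt_total = np.where(called_full, d_full, 0).sum(axis=0)
    alleles_total = 2 * called_full.sum(axis=0)
    calls = pseudohaploidize(d_full, rng)

    if loo_filter:
        fd = filter_panel.dosages
        f_called = fd != MISSING
        f_alt_tot = np.where(f_called, fd, 0).sum(axis=0)
        f_n_tot = f_called.sum(axis=0)
        f_rows = {s: filter_panel.sample_index(s) for s in members
                  if s in set(filter_panel.samples)}
        target_called = np.asarray(target_called, dtype=bool)
    else:
        sites = np.asarray(sites)

    means = np.empty(len(members))
    for m, sid in enumerate(members):
        # leave-one-out smoothed frequency of the member's own population
        alt = alt_total - np.where(called_full[m], d_full[m], 0)
        alleles = alleles_total - 2 * called_full[m]
        f = (alt + smoothing) / (alleles + 2.0 * smoothing)
        if loo_filter:
            if sid in f_rows:
                r = f_rows[sid]
                n_loo = f_n_tot - f_called[r]
                alt_loo = f_alt_tot - np.where(f_called[r], fd[r], 0)
            else:
                n_loo, alt_loo = f_n_tot, f_alt_tot
            n_panel = filter_panel.n_samples - (1 if sid in f_rows else 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                freq_loo = np.where(n_loo > 0, alt_loo / (2.0 * n_loo), np.nan)
            maf = np.minimum(freq_loo, 1.0 - freq_loo)
            member_sites = (target_called
                            & (np.nan_to_num(maf, nan=-1.0) >= min_maf)
                            & (n_loo / n_panel >= 1.0 - max_missing))
            usable = np.flatnonzero(member_sites & (calls[m] != MISSING)
                                    & (alleles > 0))
        else:
            site_ok = np.zeros(panel.n_sites, dtype=bool)
            site_ok[sites] = True
            usable = np.flatnonzero(site_ok & (calls[m] != MISSING)
                                    & (alleles > 0))
        if usable.size < n_sites_per_draw:
            raise ValueError(f"member {sid}: only {usable.size} usable sites")
        contrib = np.where(calls[m, usable] == 1, np.log(f[usable]),
                           np.log1p(-f[usable]))
        draw_means = np.empty(n_draws)
        for k in range(n_draws):
            pick = rng.choice(usable.size, size=n_sites_per_draw,
                              replace=False)
            draw_means[k] = contrib[pick].mean()
        means[m] = draw_means.mean()
    return means


@dataclass
class AssignmentReport:
    """Z-score of a target's mean draw against a modern reference."""

    sample_id: str
    population: str
    z: float
    p: float
    reference_point: str
    alternative: str
    n_reference: int


def assignment_z_test(target_dist: LnLDistribution,
                      reference_means: np.ndarray,
                      reference_point: str = "mean",
                      alternative: str = "less") -> AssignmentReport:
    """Z-test of a target against a modern population's reference values.

    ``reference_point='mean'`` centres at the reference mean;
    ``'q10'`` centres at the empirical 10% quantile of the reference values
    (the marginal-quantile comparison). The scale is always the reference
    standard deviation. ``alternative='less'`` gives the one-sided
    membership-deficit probability Phi(Z); 'two-sided' is available.
    """
    ref = np.asarray(reference_means, dtype=float)
    sigma = ref.std(ddof=1)
    if sigma == 0 or not np.isfinite(sigma):
        raise ValueError("degenerate reference distribution (zero spread)")
    if reference_point == "mean":
        centre = ref.mean()
    elif reference_point == "q10":
        centre = float(np.quantile(ref, 0.10))
    else:
        raise ValueError("reference_point must be 'mean' or 'q10'")
    z = (target_dist.mean() - centre) / sigma
    if alternative == "less":
        p = stats.norm.cdf(z)
    elif alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "two-sided":
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        raise ValueError("alternative must be 'less', 'greater' or 'two-sided'")
    return AssignmentReport(sample_id=target_dist.sample_id,
                            population=target_dist.population,
                            z=float(z), p=float(p),
                            reference_point=reference_point,
                            alternative=alternative,
                            n_reference=len(ref))


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann–Whitney/Wilcoxon rank-sum test; returns (U, p).

    Exact enumeration when the smaller sample has <= 10 values and there are
    no ties; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def assign_target(target: PseudohaploidCalls, sample_id: str,
                  panel: GenotypeMatrix, labels: pd.DataFrame,
                  populations=("JRS", "JRF"), min_maf: float = 0.1,
                  max_missing: float = 0.1, n_sites_per_draw: int = 200,
                  n_draws: int = 50, ref_n_draws: int | None = None,
                  smoothing: float = 0.5, reference_point: str = "mean",
                  rng: np.random.Generator | int | None = None
                  ) -> list[AssignmentReport]:
    """Full assignment of one target against each reference population.

    Builds the sample-optimized variant set, the smoothed frequencies, the
    target's downsampling distribution and each population's per-member
    reference distribution, then Z-tests the target against each population.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sites = sample_optimized_variant_set(target, sample_id, panel,
                                         min_maf=min_maf,
                                         max_missing=max_missing)
    freqs = pop_allele_frequencies(panel, labels, populations=list(populations),
                                   smoothing=smoothing)
    i = target.sample_index(sample_id)
    target_called = target.calls[i] != MISSING
    reports = []
    for pop in populations:
        dist = downsample_loglik(target.calls[i], freqs, pop, sites,
                                 n_sites_per_draw=n_sites_per_draw,
                                 n_draws=n_draws, rng=rng, sample_id=sample_id)
        ref = reference_distribution(panel, labels, pop,
                                     n_sites_per_draw=n_sites_per_draw,
                                     n_draws=ref_n_draws or n_draws,
                                     smoothing=smoothing, rng=rng,
                                     filter_panel=panel,
                                     target_called=target_called,
                                     min_maf=min_maf,
                                     max_missing=max_missing)
        reports.append(assignment_z_test(dist, ref,
                                         reference_point=reference_point))
    return reports


__all__ = [
    "PopFrequencies",
    "pop_allele_frequencies",
    "sample_optimized_variant_set",
    "LoglikResult",
    "sample_loglik",
    "LnLDistribution",
    "downsample_loglik",
    "reference_distribution",
    "AssignmentReport",
    "assignment_z_test",
    "wilcoxon_rank_sum",
    "assign_target",
]
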