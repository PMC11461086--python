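"""Population structure: PCA, Procrustes projection, F_ST, diversity.

PCA uses Patterson scaling — dosages centred at twice the alternate-allele
frequency and divided by sqrt(p(1-p)) — with per-site mean imputation of
missing genotypes, the standard treatment for variant panels.

Fragmentary (pseudohaploid) samples are placed by the reduced-panel
Procrustes strategy: the reference panel is restricted to the target's
genotyped sites, PCA is recomputed on that reduced panel, a least-squares
similarity transform (rotation + isotropic scale + translation; reflections
allowed, since PC signs are arbitrary) maps reduced-panel scores onto the
full-panel scores, and the target is carried through the same map.

F_ST is the Weir–Cockerham variance-components estimator with the multi-site
value formed as a ratio of sums, sum(a)/sum(a+b+c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

from paleopop.containers import MISSING, GenotypeMatrix, PseudohaploidCalls


@dataclass
class PCAResult:
    """Scores, loadings and scaling parameters of a Patterson-scaled PCA.

    ``site_index`` records which input sites survived (zero-variance sites are
    dropped); ``site_means``/``site_scales`` are aligned to it and let new
    samples be standardized identically. ``explained_variance_fraction`` is
    the fraction of total (all-component) variance per returned component.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    site_means: np.ndarray
    site_scales: np.ndarray
    site_index: np.ndarray
    samples: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(matrix: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """Patterson-scaled PCA of a genotype matrix.

    Missing dosages are mean-imputed per site; monomorphic (zero-variance)
    sites are dropped with a warning. Component signs are fixed by forcing
    the largest-magnitude loading of each component positive, so results are
    fully deterministic.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    d = matrix.dosages_float()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(d, axis=0) / 2.0
    p = np.nan_to_num(p, nan=0.0)
    scales = np.sqrt(p * (1.0 - p))
    keep = scales > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance sites")
    if not keep.any():
        raise ValueError("no polymorphic sites left for PCA")
    d = d[:, keep]
    means = 2.0 * p[keep]
    scales = scales[keep]
    x = (d - means) / scales
    x[np.isnan(x)] = 0.0  # mean imputation after centring

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2
    total = eigvals.sum()
    frac = eigvals / total if total > 0 else eigvals
    k = min(n_components, len(s))
    u, s, vt, frac = u[:, :k], s[:k], vt[:k], frac[:k]
    # deterministic sign: largest-|loading| entry of each component positive
    for comp in range(k):
        j = np.argmax(np.abs(vt[comp]))
        if vt[comp, j] < 0:
            vt[comp] *= -1.0
            u[:, comp] *= -1.0
    return PCAResult(
        scores=u * s,
        loadings=vt.T,
        explained_variance_fraction=frac,
        site_means=means,
        site_scales=scales,
        site_index=np.flatnonzero(keep),
        samples=matrix.samples.copy(),
    )


@dataclass
class ProcrustesFit:
    """Similarity transform y ~ scale * x @ rotation + translation."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray
    residual_error: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.scale * np.atleast_2d(x) @ self.rotation + self.translation


def procrustes_fit(source: np.ndarray, target: np.ndarray) -> ProcrustesFit:
    """Least-squares similarity transform mapping source points onto target.

    The rotation ranges over the full orthogonal group (reflections allowed).
    ``residual_error`` is the Frobenius norm of the remaining misfit.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValueError("source and target must have identical shapes")
    mu_s = source.mean(axis=0)
    mu_t = target.mean(axis=0)
    a = source - mu_s
    b = target - mu_t
    rotation, raw_scale = sla.orthogonal_procrustes(a, b)
    denom = float((a * a).sum())
    scale = raw_scale / denom if denom > 0 else 1.0
    translation = mu_t - scale * mu_s @ rotation
    residual = float(np.linalg.norm(scale * a @ rotation - b))
    return ProcrustesFit(rotation=rotation, scale=scale,
                         translation=translation, residual_error=residual)


def project_dosage_row(reference: GenotypeMatrix, pca_full: PCAResult,
                       dosages: np.ndarray, min_shared: int = 50,
                       n_components: int | None = None):
    """Procrustes-project one sample (dosage row, -1 missing) onto a PCA.

    Returns ``(coordinates, fit, n_shared)``. Refuses (raises ValueError) when
    the target shares fewer than ``min_shared`` genotyped sites with the
    retained panel sites — a silent projection from too little data would be
    meaningless.
    """
    dosages = np.asarray(dosages)
    if dosages.shape != (reference.n_sites,):
        raise ValueError("target dosage row does not match the panel sites")
    k = pca_full.n_components if n_components is None else n_components
    called_full = dosages[pca_full.site_index] != MISSING
    shared = pca_full.site_index[called_full]
    if len(shared) < min_shared:
        raise ValueError(
            f"target shares only {len(shared)} genotyped sites with the panel "
            f"(minimum {min_shared}); refusing to project"
        )
    reduced = reference.subset(site_idx=shared)
    pca_red = pca(reduced, n_components=k)
    fit = procrustes_fit(pca_red.scores, pca_full.scores[:, :pca_red.n_components])
    target_sites = shared[pca_red.site_index]
    x = (dosages[target_sites] - pca_red.site_means) / pca_red.site_scales
    coords_red = x @ pca_red.loadings
    return fit.apply(coords_red)[0], fit, len(shared)


def procrustes_project(reference: GenotypeMatrix, pca_full: PCAResult,
                       target: PseudohaploidCalls, min_shared: int = 50,
                       n_components: int | None = None):
    """Project every pseudohaploid target sample onto the full-panel PCA.

    Pseudohaploid calls are placed as homozygous dosages {0, 2}: a single
    sampled allele carries no heterozygosity information. Returns
    ``(coords, fits, n_shared)`` with one row/entry per target sample.
    """
    if len(target.sites) != reference.n_sites:
        raise ValueError("target and reference must share the same site table")
    coords, fits, shared_counts = [], [], []
    for i in range(target.n_samples):
        row = np.where(target.calls[i] == MISSING, MISSING,
                       target.calls[i] * 2).astype(np.int8)
        c, f, n = project_dosage_row(reference, pca_full, row,
                                     min_shared=min_shared,
                                     n_components=n_components)
        coords.append(c)
        fits.append(f)
        shared_counts.append(n)
    return np.vstack(coords), fits, np.array(shared_counts)


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST


@dataclass
class FstResult:
    """Ratio-of-sums Weir–Cockerham estimate with its component sums."""

    fst: float
    variance_components: tuple[float, float, float]
    n_sites: int
    populations: tuple[str, str]


def wc_variance_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Per-site Weir–Cockerham variance components for r populations.

    Parameters are (r, n_sites) arrays: ``n`` sample sizes (individuals),
    ``p`` alternate-allele frequencies, ``h`` observed heterozygote
    frequencies. Returns per-site (a, b, c): among-population, among
    individuals within populations, and within-individual components.
    Single-site values may be negative; that is expected of the estimator.
    """
    n = np.atleast_2d(np.asarray(n, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    h = np.atleast_2d(np.asarray(h, dtype=float))
    r = n.shape[0]
    n_bar = n.mean(axis=0)
    n_total = r * n_bar
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_total - (n**2).sum(axis=0) / n_total) / (r - 1)
        p_bar = (n * p).sum(axis=0) / n_total
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=0) / n_total
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
            / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r
            - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0
    return a, b, c


def weir_cockerham_fst(matrix: GenotypeMatrix, labels: pd.DataFrame,
                       populations: tuple[str, str]) -> FstResult:
    """Multi-site Weir–Cockerham F_ST between two populations.

    Sites where either population has no called genotypes are dropped; sites
    monomorphic across both populations contribute zero components. The
    estimate is symmetric in population order.
    """
    if len(populations) != 2:
        raise ValueError("exactly two populations required")
    rows = []
    for pop in populations:
        ids = labels.loc[labels["population"] == pop, "sample_id"]
        idx = [matrix.sample_index(s) for s in ids]
        if len(idx) < 2:
            raise ValueError(f"population {pop!r} needs at least 2 samples")
        rows.append(np.asarray(idx))
    n = np.zeros((2, matrix.n_sites))
    p = np.zeros((2, matrix.n_sites))
    h = np.zeros((2, matrix.n_sites))
    for k, idx in enumerate(rows):
        d = matrix.dosages[idx]
        called = d != MISSING
        nk = called.sum(axis=0)
        n[k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(nk > 0, np.where(called, d, 0).sum(axis=0) / (2.0 * nk), np.nan)
            h[k] = np.where(nk > 0, (d == 1).sum(axis=0) / nk, np.nan)
    usable = (n > 0).all(axis=0) & (n.mean(axis=0) > 1)
    a, b, c = wc_variance_components(n[:, usable], p[:, usable], h[:, usable])
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a_sum, b_sum, c_sum = a[ok].sum(), b[ok].sum(), c[ok].sum()
    denom = a_sum + b_sum + c_sum
    fst = a_sum / denom if denom != 0 else np.nan
    return FstResult(fst=float(fst),
                     variance_components=(float(a_sum), float(b_sum), float(c_sum)),
                     n_sites=int(ok.sum()),
                     populations=tuple(populations))


def fst_standard_error(matrix: GenotypeMatrix, labels: pd.DataFrame,
                       populations: tuple[str, str]) -> float:
    """Delete-one-site jackknife standard error of the ratio-of-sums F_ST."""
    rows = []
    for pop in populations:
        ids = labels.loc[labels["population"] == pop, "sample_id"]
        rows.append(np.asarray([matrix.sample_index(s) for s in ids]))
    n = np.zeros((2, matrix.n_sites))
    p = np.zeros((2, matrix.n_sites))
    h = np.zeros((2, matrix.n_sites))
    for k, idx in enumerate(rows):
        d = matrix.dosages[idx]
        called = d != MISSING
        nk = called.sum(axis=0)
        n[k] = nk
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(nk > 0, np.where(called, d, 0).sum(axis=0) / (2.0 * nk), np.nan)
            h[k] = np.where(nk > 0, (d == 1).sum(axis=0) / nk, np.nan)
    usable = (n > 0).all(axis=0) & (n.mean(axis=0) > 1)
    a, b, c = wc_variance_components(n[:, usable], p[:, usable], h[:, usable])
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a, t = a[ok], (a + b + c)[ok]
    a_sum, t_sum = a.sum(), t.sum()
    theta_jk = (a_sum - a) / (t_sum - t)
    m = len(a)
    return float(np.sqrt((m - 1) / m * ((theta_jk - theta_jk.mean()) ** 2).sum()))


# ---------------------------------------------------------------------------
# nuclear diversity


@dataclass
class PopDiversity:
    """Mean expected heterozygosity of one population, with per-site values."""

    population: str
    mean_het: float
    per_site: np.ndarray
    n_samples: int


def expected_heterozygosity(matrix: GenotypeMatrix, labels: pd.DataFrame,
                            populations=None) -> dict[str, PopDiversity]:
    """Per-population mean expected heterozygosity 2p(1-p) over called sites.

    A simple proxy for relative nuclear diversity; frequencies use called
    alleles only. Populations with fewer than 2 samples are rejected.
    """
    if populations is None:
        populations = [p for p in labels["population"].unique()]
    out = {}
    for pop in populations:
        ids = labels.loc[labels["population"] == pop, "sample_id"]
        idx = [matrix.sample_index(s) for s in ids]
        if len(idx) < 2:
            raise ValueError(f"population {pop!r} needs at least 2 samples")
        d = matrix.dosages[np.asarray(idx)]
        called = d != MISSING
        nk = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(nk > 0, np.where(called, d, 0).sum(axis=0) / (2.0 * nk), np.nan)
        het = 2.0 * p * (1.0 - p)
        het = het[np.isfinite(het)]
        out[pop] = PopDiversity(population=pop, mean_het=float(het.mean()),
                                per_site=het, n_samples=len(idx))
    return out


def welch_t(x, y) -> tuple[float, float]:
    """Welch's unequal-variance t-test; returns (t, two-sided p)."""
    res = stats.ttest_ind(np.asarray(x, dtype=float),
                          np.asarray(y, dtype=float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def plot_scores(pca_result: PCAResult, labels: pd.DataFrame, path,
                projected: np.ndarray | None = None,
                projected_ids=None) -> None:
    """Minimal PC1/PC2 scatter; projected targets drawn as crosses."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    lab = labels.set_index("sample_id")["population"]
    for pop in sorted(set(lab.loc[s] for s in pca_result.samples)):
        m = np.array([lab.loc[s] == pop for s in pca_result.samples])
        ax.scatter(pca_result.scores[m, 0], pca_result.scores[m, 1],
                   s=14, label=pop)
    if projected is not None:
        ax.scatter(projected[:, 0], projected[:, 1], marker="x", c="k",
                   label="projected")
    ax.set_xlabel(f"PC1 ({100 * pca_result.explained_variance_fraction[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * pca_result.explained_variance_fraction[1]:.1f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


__all__ = [
    "PCAResult",
    "pca",
    "ProcrustesFit",
    "procrustes_fit",
    "project_dosage_row",
    "procrustes_project",
    "FstResult",
    "wc_variance_components",
    "weir_cockerham_fst",
    "fst_standard_error",
    "PopDiversity",
    "expected_heterozygosity",
    "welch_t",
    "plot_scores",
]
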