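"""Synthetic nuclear panels and mitogenome alignments with known structure.

Nuclear model
-------------
A hierarchical Balding–Nichols (beta-binomial) model. Each site draws an
ancestral alternate-allele frequency ``p`` uniformly from a minor-allele band
(and its mirror image ``1 - p``). River-level frequencies are drawn from
``Beta(p (1-F_r)/F_r, (1-p)(1-F_r)/F_r)`` — the classic parameterisation in
which the Weir–Cockerham estimand equals ``F_r`` — and season-level
frequencies are drawn the same way around the river frequency with ``F_s``.
Genotypes are two binomial allele draws from the season-level frequency, so
populations are at Hardy–Weinberg equilibrium within themselves.

Defaults mirror the Chesapeake/Carolina sturgeon study design: four
populations (James and Great Pee Dee rivers, spring and fall spawning runs,
25 diploids each), 45 603 exonic variant sites, between-river differentiation
0.0060 and between-season differentiation 0.0079, and archaeological samples
that are pseudohaploid with ~98.9% site missingness (≈503 genotyped sites).

Mitogenome model
----------------
A Kingman-coalescent genealogy with infinite-sites mutations, built as two
subtrees so that a designated "historic" clade (which contains all ancient
tips) is guaranteed. Branches inside the historic clade are stretched and
ancient tips receive extra private branch length, giving the clade more
unique haplotypes and higher diversity. A configurable fraction of modern
tips are exact copies of a clade-mate, emulating the terminal polytomies of
post-bottleneck founder expansions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from paleopop.containers import (
    MISSING,
    GenotypeMatrix,
    HaplotypeAlignment,
    PseudohaploidCalls,
    make_labels,
)

POPULATIONS = ("JRS", "JRF", "PDS", "PDF")

# independent deterministic rng streams derived from the one config seed
_STREAM_NUCLEAR = 0
_STREAM_ANCIENT = 1
_STREAM_MITO = 2


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study; defaults are the study conditions."""

    n_per_pop: int = 25
    n_sites: int = 45603
    fst_river: float = 0.0060
    fst_season: float = 0.0079
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    n_ancient: int = 14
    ancient_missing_rate: float = 1.0 - 503.0 / 45603.0
    ancient_source: str = "ancestral"
    split_order: str = "river_first"
    mito_len: int = 16500
    mito_group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"JRS": 23, "JRF": 22, "PDS": 10, "PDF": 9}
    )
    n_mito_ancient: int = 6
    clade_sizes: tuple[int, int] = (28, 42)
    clade_modern_groups: Mapping[str, int] = field(
        default_factory=lambda: {"JRS": 11, "JRF": 11}
    )
    mito_mu: float = 1.0e-3
    historic_branch_scale: float = 2.0
    ancient_extra_branch: float = 1.0
    duplicate_fraction: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_pop < 1 or self.n_sites < 1 or self.n_ancient < 0:
            raise ValueError("counts must be positive")
        for name in ("fst_river", "fst_season"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise ValueError(
                    f"{name}={f} is degenerate: the Beta model requires F in (0, 1)"
                )
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if not 0.0 <= self.ancient_missing_rate < 1.0:
            raise ValueError(
                "ancient_missing_rate must be in [0, 1): rate 1.0 leaves no data"
            )
        if self.split_order not in ("river_first", "season_first"):
            raise ValueError("split_order must be 'river_first' or 'season_first'")
        if self.ancient_source != "ancestral" and self.ancient_source not in POPULATIONS:
            raise ValueError(f"unknown ancient_source {self.ancient_source!r}")
        if not 0.0 <= self.duplicate_fraction <= 1.0:
            raise ValueError("duplicate_fraction must be in [0, 1]")
        n_modern = sum(self.mito_group_sizes.values())
        total = n_modern + self.n_mito_ancient
        if sum(self.clade_sizes) != total:
            raise ValueError(
                f"clade_sizes {self.clade_sizes} must sum to the {total} mito tips"
            )
        n_clade_modern = sum(self.clade_modern_groups.values())
        if n_clade_modern + self.n_mito_ancient != self.clade_sizes[0]:
            raise ValueError(
                "clade_modern_groups + ancient tips must equal the historic clade size"
            )
        for grp, k in self.clade_modern_groups.items():
            if k > self.mito_group_sizes.get(grp, 0):
                raise ValueError(f"clade asks for more {grp} tips than exist")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _beta_around(freq: np.ndarray, fst: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols draw of daughter frequencies around ``freq``."""
    scale = (1.0 - fst) / fst
    out = rng.beta(freq * scale, (1.0 - freq) * scale)
    # guard against exact 0/1 from extreme Beta draws; keeps logs finite later
    return np.clip(out, 1e-12, 1.0 - 1e-12)


def simulate_nuclear_panel(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate the four-population modern diploid panel.

    Returns the genotype matrix (with simulation-truth frequencies attached)
    and a label frame (sample_id, population, era='modern'). Deterministic
    given the config (including its seed).
    """
    rng = _rng(config, _STREAM_NUCLEAR)
    lo, hi = config.ancestral_maf_range
    p = rng.uniform(lo, hi, size=config.n_sites)
    flip = rng.random(config.n_sites) < 0.5
    p = np.where(flip, 1.0 - p, p)

    if config.split_order == "river_first":
        james = _beta_around(p, config.fst_river, rng)
        peedee = _beta_around(p, config.fst_river, rng)
        pop_freq = {
            "JRS": _beta_around(james, config.fst_season, rng),
            "JRF": _beta_around(james, config.fst_season, rng),
            "PDS": _beta_around(peedee, config.fst_season, rng),
            "PDF": _beta_around(peedee, config.fst_season, rng),
        }
    else:  # season_first
        spring = _beta_around(p, config.fst_season, rng)
        fall = _beta_around(p, config.fst_season, rng)
        pop_freq = {
            "JRS": _beta_around(spring, config.fst_river, rng),
            "JRF": _beta_around(fall, config.fst_river, rng),
            "PDS": _beta_around(spring, config.fst_river, rng),
            "PDF": _beta_around(fall, config.fst_river, rng),
        }

    blocks, ids, pops = [], [], []
    for pop in POPULATIONS:
        g = rng.binomial(2, pop_freq[pop],
                         size=(config.n_per_pop, config.n_sites)).astype(np.int8)
        blocks.append(g)
        ids.extend(f"{pop}{i + 1:03d}" for i in range(config.n_per_pop))
        pops.extend([pop] * config.n_per_pop)

    sites = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, config.n_sites + 1),
         "ref": "A", "alt": "G"}
    )
    matrix = GenotypeMatrix(
        samples=np.array(ids, dtype=object),
        sites=sites,
        dosages=np.vstack(blocks),
        ancestral_freq=p,
        pop_freqs=pd.DataFrame(pop_freq),
    )
    labels = make_labels(ids, pops, "modern")
    return matrix, labels


def pseudohaploidize(dosages: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Sample one allele per site from diploid dosages.

    Homozygotes are deterministic (0 -> ref, 2 -> alt); heterozygotes yield
    each allele with probability 1/2. Missing stays missing.
    """
    dosages = np.asarray(dosages)
    coin = rng.integers(0, 2, size=dosages.shape).astype(np.int8)
    calls = np.where(dosages == 1, coin, dosages // 2).astype(np.int8)
    calls[dosages == MISSING] = MISSING
    return calls


def degrade_to_ancient(panel: GenotypeMatrix, labels: pd.DataFrame,
                       config: SimConfig) -> PseudohaploidCalls:
    """Draw ancient samples, pseudohaploidize them and mask most sites.

    Ancient individuals are fresh diploid draws from the configured source —
    by default the pre-split ancestral frequency pool (the null under which
    they belong to neither present-day seasonal group), or a named modern
    population's simulation-truth frequencies (the alternative hypothesis,
    e.g. fall-run origin). Each sample keeps an independent uniformly random
    ``1 - ancient_missing_rate`` fraction of sites.
    """
    rng = _rng(config, _STREAM_ANCIENT)
    if config.ancient_source == "ancestral":
        if panel.ancestral_freq is None:
            raise ValueError("panel carries no ancestral frequencies")
        freq = panel.ancestral_freq
    else:
        if panel.pop_freqs is None:
            raise ValueError("panel carries no population frequencies")
        freq = panel.pop_freqs[config.ancient_source].to_numpy()

    n = config.n_ancient
    diploid = rng.binomial(2, freq, size=(n, panel.n_sites)).astype(np.int8)
    calls = pseudohaploidize(diploid, rng)
    keep = rng.random((n, panel.n_sites)) >= config.ancient_missing_rate
    calls[~keep] = MISSING
    ids = np.array([f"ANC{i + 1:03d}" for i in range(n)], dtype=object)
    return PseudohaploidCalls(samples=ids, sites=panel.sites, calls=calls)


def ancient_labels(config: SimConfig) -> pd.DataFrame:
    """Label frame for the simulated ancient samples."""
    ids = [f"ANC{i + 1:03d}" for i in range(config.n_ancient)]
    pop = ("ancestral" if config.ancient_source == "ancestral"
           else config.ancient_source)
    return make_labels(ids, pop, "ancient")


# ---------------------------------------------------------------------------
# mitogenome alignment simulator


def _coalescent_topology(n_tips: int, rng: np.random.Generator,
                         branch_scale: float = 1.0):
    """Kingman coalescent on ``n_tips``: returns (parents, branch_lengths).

    Nodes 0..n_tips-1 are tips; internal nodes follow. Times are in
    coalescent units; branch lengths are child-to-parent spans scaled by
    ``branch_scale``.
    """
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=int)
    time = np.zeros(n_nodes)
    active = list(range(n_tips))
    t = 0.0
    next_node = n_tips
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = next_node
        time[next_node] = t
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(next_node)
        next_node += 1
    lengths = np.zeros(n_nodes)
    has_parent = parent >= 0
    lengths[has_parent] = (time[parent[has_parent]] - time[np.flatnonzero(has_parent)])
    return parent, lengths * branch_scale, time[-1]


def _descendant_tips(parent: np.ndarray, n_tips: int) -> list[set[int]]:
    n_nodes = len(parent)
    desc: list[set[int]] = [set() for _ in range(n_nodes)]
    for tip in range(n_tips):
        node = tip
        while node >= 0:
            desc[node].add(tip)
            node = parent[node]
    return desc


def simulate_mito_alignment(config: SimConfig) -> HaplotypeAlignment:
    """Simulate the mitogenome alignment with a designated historic clade.

    Two coalescent subtrees are built — the historic clade's modern members
    (branches stretched by ``historic_branch_scale``) and the remainder —
    and joined at a root. Mutations are Poisson on branches at ``mito_mu``
    per site per coalescent unit under infinite sites (each mutation
    occupies a distinct column). Each ancient tip then joins the historic
    clade independently: it inherits the mutation path above a randomly
    chosen lineage of the modern clade tree (so the ancients are dispersed
    across the clade) and gains ``ancient_extra_branch`` of private branch
    length. Finally ``duplicate_fraction`` of modern tips within each
    group x clade cell are overwritten with a clade-mate's haplotype
    (terminal polytomies).
    """
    rng = _rng(config, _STREAM_MITO)
    n_clade, n_rest = config.clade_sizes

    # tip bookkeeping: ids, groups, eras, clade membership
    ids: list[str] = []
    groups: list[str] = []
    eras: list[str] = []
    in_clade: list[bool] = []
    clade_quota = dict(config.clade_modern_groups)
    for grp, size in config.mito_group_sizes.items():
        k_in = clade_quota.get(grp, 0)
        for i in range(size):
            ids.append(f"{grp}m{i + 1:02d}")
            groups.append(grp)
            eras.append("modern")
            in_clade.append(i < k_in)
    for i in range(config.n_mito_ancient):
        ids.append(f"ANCm{i + 1:02d}")
        groups.append("ancient")
        eras.append("ancient")
        in_clade.append(True)
    ids_arr = np.array(ids, dtype=object)
    in_clade_arr = np.array(in_clade)
    eras_arr = np.array(eras, dtype=object)
    clade_tips = np.flatnonzero(in_clade_arr)
    rest_tips = np.flatnonzero(~in_clade_arr)
    if len(clade_tips) != n_clade or len(rest_tips) != n_rest:
        raise ValueError("clade bookkeeping mismatch")

    # accumulate per-tip mutation sets
    n_total = len(ids)
    mutations_of_tip: list[list[int]] = [[] for _ in range(n_total)]
    n_positions = config.mito_len
    free_positions = rng.permutation(n_positions)
    cursor = 0

    def take_positions(k: int) -> np.ndarray:
        nonlocal cursor
        if cursor + k > n_positions:
            raise ValueError(
                f"mito_len={config.mito_len} too small for the requested "
                f"mutation count (needed > {cursor + k})"
            )
        out = free_positions[cursor:cursor + k]
        cursor += k
        return out

    def drop_mutations(tips: np.ndarray, branch_scale: float):
        """Coalescent subtree with Poisson mutations; returns branch records
        as (ancestor-node chain per node, positions per node) for grafting."""
        if len(tips) <= 1:
            return None
        parent, lengths, _ = _coalescent_topology(len(tips), rng, branch_scale)
        desc = _descendant_tips(parent, len(tips))
        positions_of_node: dict[int, np.ndarray] = {}
        for node in range(len(parent)):
            if parent[node] < 0:
                continue
            n_mut = rng.poisson(lengths[node] * config.mito_mu * config.mito_len)
            if n_mut == 0:
                continue
            pos = take_positions(n_mut)
            positions_of_node[node] = pos
            for local_tip in desc[node]:
                mutations_of_tip[tips[local_tip]].extend(pos.tolist())
        return parent, positions_of_node

    # ancient lineages join the historic clade as independently placed
    # relatives of the modern clade tree (one random attachment lineage each),
    # so they are dispersed across the clade rather than forming their own
    # recent subcluster — mirroring how samples separated by centuries relate
    # to a surviving clade.
    modern_clade = clade_tips[eras_arr[clade_tips] == "modern"]
    ancient_tips = clade_tips[eras_arr[clade_tips] == "ancient"]
    clade_tree = drop_mutations(modern_clade, config.historic_branch_scale)
    if clade_tree is not None:
        parent, positions_of_node = clade_tree
        n_nodes = len(parent)
        for tip in ancient_tips:
            attach = int(rng.integers(0, n_nodes))
            node = parent[attach]  # share branches strictly above the anchor
            while node >= 0:
                if node in positions_of_node:
                    mutations_of_tip[tip].extend(positions_of_node[node].tolist())
                node = parent[node]
    drop_mutations(rest_tips, 1.0)
    # root split between the two subtrees: mutations private to one side
    for tips in (clade_tips, rest_tips):
        n_mut = rng.poisson(1.0 * config.mito_mu * config.mito_len)
        if n_mut:
            pos = take_positions(n_mut)
            for tip in tips:
                mutations_of_tip[tip].extend(pos.tolist())
    # extra private branch length on ancient tips (older, more divergent)
    for tip in np.flatnonzero(eras_arr == "ancient"):
        n_mut = rng.poisson(config.ancient_extra_branch * config.mito_mu
                            * config.mito_len)
        if n_mut:
            mutations_of_tip[tip].extend(take_positions(n_mut).tolist())

    # build sequences: random ancestral sequence, derived base at mutated cols
    bases = np.frombuffer(b"ACGT", dtype="S1")
    ancestral = bases[rng.integers(0, 4, size=n_positions)]
    derived_shift = rng.integers(1, 4, size=n_positions)
    seqs = np.tile(ancestral, (n_total, 1))
    base_index = np.empty(256, dtype=int)
    for i, b in enumerate(b"ACGT"):
        base_index[b] = i
    anc_idx = base_index[ancestral.view(np.uint8)]
    for tip, positions in enumerate(mutations_of_tip):
        if not positions:
            continue
        pos = np.asarray(positions)
        seqs[tip, pos] = bases[(anc_idx[pos] + derived_shift[pos]) % 4]

    # terminal polytomies: duplicate haplotypes within group x clade cells
    groups_arr = np.array(groups, dtype=object)
    for grp in config.mito_group_sizes:
        for clade_side in (True, False):
            cell = np.flatnonzero((groups_arr == grp)
                                  & (in_clade_arr == clade_side)
                                  & (eras_arr == "modern"))
            if len(cell) < 2:
                continue
            n_dup = int(np.floor(config.duplicate_fraction * len(cell)))
            if n_dup == 0:
                continue
            seed_tip = cell[0]
            copies = rng.choice(cell[1:], size=min(n_dup, len(cell) - 1),
                                replace=False)
            seqs[copies] = seqs[seed_tip]

    return HaplotypeAlignment(ids=ids_arr, seqs=seqs, groups=groups_arr,
                              eras=eras_arr, in_clade=in_clade_arr)


__all__ = [
    "POPULATIONS",
    "SimConfig",
    "simulate_nuclear_panel",
    "pseudohaploidize",
    "degrade_to_ancient",
    "ancient_labels",
    "simulate_mito_alignment",
]
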