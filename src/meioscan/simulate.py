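"""Generative model for low-coverage single-gamete sequencing experiments.

The simulator produces sparse gamete genotype matrices with known truth, for
benchmarking every stage of the pipeline:

1. draw donor haplotype 1 as i.i.d. Bernoulli(0.5) alleles and set
   haplotype 2 to its complement;
2. trace each gamete through the haplotypes, drawing a Poisson number of
   crossovers (uniform over inter-SNP gaps, without replacement) and
   inverting alleles after each one;
3. mask genotypes down to a target coverage: the missing genotype rate is
   the Poisson zero-class probability ``MGR = exp(-coverage)``, and exactly
   ``round(MGR * cells)`` entries are hidden, uniformly without replacement;
4. invert alleles at ``round(error_rate * observed cells)`` uniformly chosen
   observed cells to emulate genotyping error;
5. drop sites where fewer than both alleles remain observed (they would be
   indistinguishable from homozygous sites in real data).

A variant of the model plants transmission distortion: gametes carrying a
designated allele at a causal SNP are removed from an enlarged pool with
probability ``2 - 1/k``, which makes the favoured allele's realized
transmission rate equal ``k``.

Crossover "positions" live on inter-SNP gap indices (gap ``i`` separates
SNPs ``i`` and ``i+1``, 0-based).  By default SNP positions are the 1-based
site indices; a fixed inter-SNP spacing (e.g. 1000 bp, matching a pairwise
nucleotide diversity of one hetSNP per kilobase) can be requested for
breakpoint-resolution studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .matrix import NA, GameteMatrix, NoInformativeSitesError


@dataclass
class SimParams:
    """Study-design parameters of the generative model."""

    n_gametes: int = 1000
    n_hetsnps: int = 30_000  # underlying hetSNP count before masking/filtering
    coverage: float = 0.01  # sequencing depth per cell, x
    recomb_rate: float = 1.0  # mean crossovers per chromosome per gamete
    error_rate: float = 0.005  # genotype inversion probability
    seed: int = 0
    td_k: float | None = None  # transmission rate of the favoured allele
    causal_index: int | None = None  # underlying SNP index of the causal site
    bp_spacing: int | None = None  # fixed inter-SNP spacing in bp (None: index coordinates)

    def __post_init__(self) -> None:
        if self.n_gametes < 1 or self.n_hetsnps < 2:
            raise ValueError("need at least 1 gamete and 2 hetSNPs")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.recomb_rate < 0:
            raise ValueError("recomb_rate must be >= 0")
        if self.td_k is not None and not 0.5 <= self.td_k < 1.0:
            raise ValueError("td_k must be in [0.5, 1)")

    @property
    def positions(self) -> np.ndarray:
        spacing = self.bp_spacing or 1
        return spacing * np.arange(1, self.n_hetsnps + 1, dtype=np.int64)


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated gamete matrix."""

    h1: np.ndarray  # underlying haplotype 1, int8, no NA
    h2: np.ndarray
    genotypes: np.ndarray  # dense truth matrix (underlying sites x gametes)
    breakpoints: list[np.ndarray]  # per gamete: sorted gap indices (gap i = between SNP i, i+1)
    positions: np.ndarray  # positions of all underlying sites
    kept_sites: np.ndarray  # indices of sites surviving the informative filter
    masked_cells: tuple[np.ndarray, np.ndarray]  # (site_idx, gamete_idx) of masked entries
    error_cells: tuple[np.ndarray, np.ndarray]  # (site_idx, gamete_idx) of inverted entries
    realized_mgr: float
    causal_index: int | None = None
    favored_allele: int | None = None
    causal_kept: bool | None = None


def mgr(coverage: float) -> float:
    """Missing genotype rate at a sequencing depth: ``exp(-coverage)``.

    The Poisson zero-class probability — the chance that a site in a cell
    receives no reads at all.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    return math.exp(-coverage)


def _sample_cells(rng: np.random.Generator, n_total: int, k: int) -> np.ndarray:
    """Sample ``k`` distinct flat cell indices from ``range(n_total)``.

    Rejection sampling with resampling of duplicates; avoids materialising a
    permutation of very large matrices.
    """
    if k < 0 or k > n_total:
        raise ValueError("cannot sample more cells than exist")
    if k == n_total:
        return np.arange(n_total, dtype=np.int64)
    if k > n_total // 2:  # sample the complement instead
        drop = _sample_cells(rng, n_total, n_total - k)
        mask = np.ones(n_total, dtype=bool)
        mask[drop] = False
        return np.flatnonzero(mask)
    chosen = np.unique(rng.integers(0, n_total, size=k))
    while chosen.size < k:
        extra = rng.integers(0, n_total, size=(k - chosen.size) * 2 + 8)
        chosen = np.unique(np.concatenate([chosen, extra]))
    if chosen.size > k:
        chosen = rng.permutation(chosen)[:k]
        chosen.sort()
    return chosen


def _trace_gametes(rng: np.random.Generator, h1: np.ndarray, n_gametes: int, recomb_rate: float) -> tuple[np.ndarray, list[np.ndarray]]:
    """Trace gametes through the haplotypes; returns (matrix, breakpoints)."""
    n = h1.size
    n_gaps = n - 1
    counts = rng.poisson(recomb_rate, size=n_gametes)
    counts = np.minimum(counts, n_gaps)  # cannot place more distinct gaps than exist
    starts = rng.integers(0, 2, size=n_gametes)
    geno = np.empty((n, n_gametes), dtype=np.int8)
    breakpoints: list[np.ndarray] = []
    h = (h1, (1 - h1).astype(np.int8))
    for j in range(n_gametes):
        col = h[starts[j]].copy()
        if counts[j]:
            gaps = np.sort(rng.choice(n_gaps, size=counts[j], replace=False))
            for g in gaps:
                col[g + 1 :] = 1 - col[g + 1 :]
        else:
            gaps = np.empty(0, dtype=np.int64)
        geno[:, j] = col
        breakpoints.append(gaps.astype(np.int64))
    return geno, breakpoints


def mask_to_coverage(dense: np.ndarray, coverage: float, rng: np.random.Generator) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Mask ``round(MGR * cells)`` entries (uniform, without replacement)."""
    rate = mgr(coverage)
    n_total = dense.size
    n_mask = int(round(rate * n_total))
    flat_idx = _sample_cells(rng, n_total, n_mask)
    sparse = dense.copy()
    cells = np.unravel_index(flat_idx, dense.shape)
    sparse[cells] = NA
    return sparse, cells


def inject_errors(sparse: np.ndarray, error_rate: float, rng: np.random.Generator) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Invert alleles at ``round(rate * observed cells)`` observed cells."""
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    out = sparse.copy()
    obs_flat = np.flatnonzero(sparse.reshape(-1) != NA)
    n_err = int(round(error_rate * obs_flat.size))
    if n_err == 0:
        return out, (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    pick = obs_flat[_sample_cells(rng, obs_flat.size, n_err)]
    cells = np.unravel_index(pick, sparse.shape)
    out[cells] = 1 - out[cells]
    return out, cells


def _finalize(
    p: SimParams,
    rng: np.random.Generator,
    truth_geno: np.ndarray,
    breakpoints: list[np.ndarray],
    h1: np.ndarray,
    causal_index: int | None = None,
    favored_allele: int | None = None,
) -> tuple[GameteMatrix, SimTruth]:
    """Shared masking / error / filtering tail of the generative model."""
    sparse, masked_cells = mask_to_coverage(truth_geno, p.coverage, rng)
    sparse, error_cells = inject_errors(sparse, p.error_rate, rng)
    has0 = (sparse == 0).any(axis=1)
    has1 = (sparse == 1).any(axis=1)
    kept = np.flatnonzero(has0 & has1)
    if kept.size == 0:
        raise NoInformativeSitesError("no observable hetSNPs survived masking")
    positions = p.positions
    gm = GameteMatrix(
        positions=positions[kept],
        gamete_ids=[f"g{j}" for j in range(p.n_gametes)],
        genotypes=sparse[kept],
    )
    truth = SimTruth(
        h1=h1,
        h2=(1 - h1).astype(np.int8),
        genotypes=truth_geno,
        breakpoints=breakpoints,
        positions=positions,
        kept_sites=kept,
        masked_cells=masked_cells,
        error_cells=error_cells,
        realized_mgr=float((sparse == NA).mean()),
        causal_index=causal_index,
        favored_allele=favored_allele,
        causal_kept=None if causal_index is None else bool(np.isin(causal_index, kept)),
    )
    return gm, truth


def simulate_dataset(p: SimParams) -> tuple[GameteMatrix, SimTruth]:
    """Run the full generative model for a balanced-transmission dataset."""
    if p.td_k is not None:
        return simulate_td_dataset(p)
    rng = np.random.default_rng(p.seed)
    h1 = rng.integers(0, 2, size=p.n_hetsnps).astype(np.int8)
    truth_geno, breakpoints = _trace_gametes(rng, h1, p.n_gametes, p.recomb_rate)
    return _finalize(p, rng, truth_geno, breakpoints, h1)


def td_removal_fraction(k: float) -> float:
    """Carrier-removal fraction producing transmission rate ``k``: ``2 - 1/k``."""
    if not 0.5 <= k < 1.0:
        raise ValueError("k must be in [0.5, 1)")
    return 2.0 - 1.0 / k


def simulate_td_dataset(p: SimParams, max_retries: int = 4) -> tuple[GameteMatrix, SimTruth]:
    """Generative model with planted transmission distortion.

    An enlarged gamete pool is generated; each gamete carrying the
    under-transmitted allele at the causal SNP is removed with probability
    ``f = 2 - 1/k``, and the survivors are down-sampled to ``n_gametes``.
    The pool is enlarged and regenerated if it is exhausted.
    """
    if p.td_k is None:
        raise ValueError("simulate_td_dataset requires td_k")
    rng = np.random.default_rng(p.seed)
    f = td_removal_fraction(p.td_k)
    h1 = rng.integers(0, 2, size=p.n_hetsnps).astype(np.int8)
    causal = (
        int(rng.integers(0, p.n_hetsnps)) if p.causal_index is None else int(p.causal_index)
    )
    # the favoured allele is haplotype 1's allele at the causal site; gametes
    # carrying the complementary (haplotype 2) allele there are culled
    favored = int(h1[causal])

    expected_keep = 0.5 + 0.5 * (1.0 - f)
    pool_factor = 1.25 / expected_keep
    for _ in range(max_retries + 1):
        pool_n = max(p.n_gametes, int(math.ceil(p.n_gametes * pool_factor)))
        pool_geno, pool_bp = _trace_gametes(rng, h1, pool_n, p.recomb_rate)
        carrier = pool_geno[causal] != favored
        removed = carrier & (rng.random(pool_n) < f)
        survivors = np.flatnonzero(~removed)
        if survivors.size >= p.n_gametes:
            chosen = np.sort(rng.choice(survivors, size=p.n_gametes, replace=False))
            truth_geno = pool_geno[:, chosen]
            breakpoints = [pool_bp[j] for j in chosen]
            return _finalize(p, rng, truth_geno, breakpoints, h1, causal, favored)
        pool_factor *= 2.0
    raise RuntimeError("gamete pool exhausted while enforcing the transmission rate")
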