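"""Transmission-distortion statistics for imputed gamete genotypes.

Under Mendel's first law a heterozygous donor transmits either allele to a
gamete with probability 1/2, so at every hetSNP the allele counts across the
gamete pool follow Binomial(n, 0.5).  The scan applies an exact two-tailed
binomial test per site.  Because sperm from one donor share entire haplotype
tracts, the tests are extremely correlated; the Bonferroni correction
therefore divides the family alpha by the *effective* number of independent
tests, estimated from the eigenvalues of the SNP correlation matrix (the
simpleM approach).  A complementary global statistic — mean pairwise allele
sharing between gametes at LD-pruned SNPs — detects diffuse distortion that
no single site would reveal, and is calibrated against matched null
simulations.  Power calculators cover the gamete-count binomial design, the
pedigree TDT (McNemar) design, and the full-pipeline extreme-distortion
scenario.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .matrix import NA, NoInformativeSitesError
from .imputation import HmmParams, ImputedMatrix, impute, superimpose_observed
from .phasing import DiscordantWindowsError, phase
from .simulate import SimParams, simulate_td_dataset, simulate_dataset, _trace_gametes

logger = logging.getLogger(__name__)

DEFAULT_FAMILY_ALPHA = 0.05
DEFAULT_VAR_FRACTION = 0.995  # simpleM's published eigenvalue-mass cutoff


@dataclass
class TDScanResult:
    """Per-hetSNP transmission counts and exact binomial p-values."""

    positions: np.ndarray
    n0: np.ndarray
    n1: np.ndarray
    pvalues: np.ndarray
    alpha_adjusted: float | None = None

    @property
    def fraction(self) -> np.ndarray:
        """Transmission fraction of allele 1 per site."""
        return self.n1 / (self.n0 + self.n1)

    @property
    def significant(self) -> np.ndarray:
        if self.alpha_adjusted is None:
            raise ValueError("no adjusted significance threshold set")
        return self.pvalues < self.alpha_adjusted

    def lead(self) -> tuple[int, float, float]:
        """(position, p-value, transmission fraction) of the minimum-p site."""
        i = int(np.argmin(self.pvalues))
        return int(self.positions[i]), float(self.pvalues[i]), float(self.fraction[i])


@dataclass
class PowerResult:
    """Monte-Carlo rejection rate of a TD test under a fixed design."""

    n_gametes: int
    k: float
    alpha: float
    n_trials: int
    power: float
    test: str  # binomial / tdt_mcnemar / pipeline_extreme


def exact_binom_two_sided(n: int, p0: float = 0.5) -> np.ndarray:
    """Exact two-tailed binomial p-values for every count 0..n.

    The p-value at count k sums the probabilities of all outcomes no more
    likely than k (the standard minimum-likelihood two-sided rule), with a
    small relative tolerance guarding against floating-point ties.
    """
    k = np.arange(n + 1)
    pmf = stats.binom.pmf(k, n, p0)
    order = np.argsort(pmf, kind="stable")
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    idx = np.searchsorted(sorted_pmf, pmf * (1.0 + 1e-7), side="right")
    return np.minimum(cum[np.maximum(idx, 1) - 1], 1.0)


def binomial_scan(imp: ImputedMatrix, alpha_adjusted: float | None = None) -> TDScanResult:
    """Exact two-tailed binomial test of balanced transmission per hetSNP.

    Expects the imputed matrix *with* superimposed observations (the final
    genotype calls).  Sites with zero non-NA calls are skipped with a warning.
    """
    geno = imp.genotypes
    n1 = (geno == 1).sum(axis=1).astype(np.int64)
    n0 = (geno == 0).sum(axis=1).astype(np.int64)
    total = n0 + n1
    usable = total > 0
    if not usable.all():
        logger.warning("skipping %d site(s) with zero genotype calls", int((~usable).sum()))
    positions = imp.positions[usable]
    n0u, n1u, totu = n0[usable], n1[usable], total[usable]
    pvals = np.empty(n1u.size, dtype=np.float64)
    for n in np.unique(totu):
        table = exact_binom_two_sided(int(n))
        sel = totu == n
        pvals[sel] = table[n1u[sel]]
    return TDScanResult(positions=positions, n0=n0u, n1=n1u, pvalues=pvals, alpha_adjusted=alpha_adjusted)


def _corr_from_genotypes(block: np.ndarray) -> np.ndarray:
    """SNP x SNP correlation for a block of genotype rows; NAs are filled
    with the row mean (they are rare in imputed matrices)."""
    x = block.astype(np.float64)
    x[block == NA] = np.nan
    means = np.nanmean(x, axis=1)
    fill = np.where(np.isnan(x), means[:, None], x)
    return np.corrcoef(fill)


def effective_tests(
    genotypes: np.ndarray,
    var_fraction: float = DEFAULT_VAR_FRACTION,
    block_size: int = 1000,
) -> int:
    """Effective number of independent tests (simpleM-style PCA estimate).

    The SNP correlation matrix is eigendecomposed in blocks of
    ``block_size`` consecutive SNPs; per block, the effective test count is
    the smallest number of top eigenvalues whose sum reaches
    ``var_fraction`` of the total.  Block counts are summed.  Constant SNP
    rows (undefined variance) are dropped with a warning.
    """
    geno = np.asarray(genotypes)
    obs = geno != NA
    x = np.where(obs, geno, 0).astype(np.float64)
    n_obs = obs.sum(axis=1)
    sums = x.sum(axis=1)
    constant = np.zeros(len(geno), dtype=bool)
    with np.errstate(invalid="ignore"):
        constant = (n_obs < 2) | (sums == 0) | (sums == n_obs)
    if constant.any():
        logger.warning("dropping %d constant SNP row(s) before correlation", int(constant.sum()))
    rows = np.flatnonzero(~constant)
    if rows.size == 0:
        raise ValueError("no variable SNPs; effective test count undefined")
    m_eff = 0
    for start in range(0, rows.size, block_size):
        block = geno[rows[start : start + block_size]]
        if block.shape[0] == 1:
            m_eff += 1
            continue
        corr = _corr_from_genotypes(block)
        eigs = np.linalg.eigvalsh(corr)[::-1]
        eigs = np.clip(eigs, 0.0, None)
        cum = np.cumsum(eigs)
        target = var_fraction * cum[-1]
        m_eff += int(np.searchsorted(cum, target - 1e-12) + 1)
    return m_eff


def significance_threshold(m_eff_total: float, family_alpha: float = DEFAULT_FAMILY_ALPHA) -> float:
    """Bonferroni threshold over the effective test count (all donors pooled)."""
    if m_eff_total < 1:
        raise ValueError("m_eff_total must be >= 1")
    return family_alpha / m_eff_total


def prune_ld(
    genotypes: np.ndarray,
    window: int = 50,
    step: int = 5,
    vif_threshold: float = 2.0,
) -> np.ndarray:
    """Indices of SNPs in approximate linkage equilibrium (VIF pruning).

    Mirrors the classic sliding-window variance-inflation-factor rule
    (window of 50 SNPs, step 5, VIF < 2): within each window the SNP with
    the largest VIF (diagonal of the inverted correlation matrix) is removed
    until all remaining VIFs fall below the threshold.
    """
    geno = np.asarray(genotypes)
    n_sites = geno.shape[0]
    obs = geno != NA
    n_obs = obs.sum(axis=1)
    sums = np.where(obs, geno, 0).sum(axis=1)
    keep = ~((n_obs < 2) | (sums == 0) | (sums == n_obs))  # constant rows out
    for start in range(0, max(n_sites - window, 0) + 1, step):
        idx = np.flatnonzero(keep[start : start + window]) + start
        while idx.size >= 2:
            corr = _corr_from_genotypes(geno[idx])
            # light ridge keeps perfectly collinear windows invertible
            inv = np.linalg.inv(corr + 1e-8 * np.eye(idx.size))
            vif = np.diag(inv)
            worst = int(np.argmax(vif))
            if vif[worst] <= vif_threshold:
                break
            keep[idx[worst]] = False
            idx = np.delete(idx, worst)
        if start + window >= n_sites:
            break
    return np.flatnonzero(keep)


def pairwise_allele_sharing(genotypes: np.ndarray) -> float:
    """Mean fraction of equal alleles over all gamete pairs.

    Per pair, the fraction is computed over mutually non-NA sites; pairs
    with no comparable site are excluded from the mean.
    """
    geno = np.asarray(genotypes)
    n_gam = geno.shape[1]
    if n_gam < 2:
        raise ValueError("allele sharing needs at least 2 gametes")
    g1 = (geno == 1).astype(np.float64)
    g0 = (geno == 0).astype(np.float64)
    o = (geno != NA).astype(np.float64)
    eq = g1.T @ g1 + g0.T @ g0
    den = o.T @ o
    iu = np.triu_indices(n_gam, k=1)
    num_pairs = eq[iu]
    den_pairs = den[iu]
    usable = den_pairs > 0
    if not usable.any():
        raise ValueError("no gamete pair shares an observed site")
    return float((num_pairs[usable] / den_pairs[usable]).mean())


def global_allele_sharing(
    imp: ImputedMatrix,
    window: int = 50,
    step: int = 5,
    vif_threshold: float = 2.0,
) -> tuple[float, np.ndarray]:
    """(mean pairwise sharing, pruned SNP indices) for one donor chromosome."""
    pruned = prune_ld(imp.genotypes, window=window, step=step, vif_threshold=vif_threshold)
    if pruned.size == 0:
        raise ValueError("LD pruning removed all SNPs")
    return pairwise_allele_sharing(imp.genotypes[pruned]), pruned


def allele_sharing_null(
    observed_mean: float,
    n_gametes: int,
    n_snps: int,
    crossover_counts: np.ndarray | float,
    n_sims: int = 500,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """One-tailed p-value of the observed sharing against matched nulls.

    Each null replicate re-runs the generative model without missing data or
    errors, matched on gamete number, (pruned) SNP count, and crossover
    counts, and records the mean pairwise sharing.  The p-value is the
    fraction of null means >= the observed mean.
    """
    rng = np.random.default_rng(seed)
    counts = np.asarray(crossover_counts)
    null_means = np.empty(n_sims)
    for s in range(n_sims):
        h1 = rng.integers(0, 2, size=n_snps).astype(np.int8)
        if counts.ndim == 0:  # a rate: draw Poisson counts internally
            geno, _ = _trace_gametes(rng, h1, n_gametes, float(counts))
        else:
            geno = _trace_with_counts(rng, h1, counts)
        null_means[s] = pairwise_allele_sharing(geno)
    p = float((null_means >= observed_mean).mean())
    return p, null_means


def _trace_with_counts(rng: np.random.Generator, h1: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Trace gametes using a fixed per-gamete crossover count."""
    n = h1.size
    n_gaps = n - 1
    geno = np.empty((n, counts.size), dtype=np.int8)
    h2 = (1 - h1).astype(np.int8)
    for j, c in enumerate(np.minimum(counts.astype(int), n_gaps)):
        col = (h1 if rng.integers(0, 2) == 0 else h2).copy()
        if c:
            for g in np.sort(rng.choice(n_gaps, size=c, replace=False)):
                col[g + 1 :] = 1 - col[g + 1 :]
        geno[:, j] = col
    return geno


def power_binomial(
    n_gametes: int,
    k: float,
    alpha: float,
    n_trials: int = 1000,
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo power of the exact two-tailed binomial test against 0.5.

    Each trial draws an allele count from Binomial(n, k) — full knowledge of
    every gamete's genotype at the site — and rejects when the exact
    two-tailed p-value falls below ``alpha``.
    """
    if not 0.5 <= k <= 1.0:
        raise ValueError("k must be in [0.5, 1]")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    table = exact_binom_two_sided(n_gametes)
    draws = rng.binomial(n_gametes, k, size=n_trials)
    power = float((table[draws] < alpha).mean())
    return PowerResult(n_gametes, k, alpha, n_trials, power, "binomial")


def tdt_statistic(b: int | np.ndarray, c: int | np.ndarray) -> np.ndarray:
    """McNemar chi-square statistic (b - c)^2 / (b + c) of the TDT."""
    b = np.asarray(b, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    total = b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(total > 0, (b - c) ** 2 / np.where(total > 0, total, 1.0), 0.0)
    return x


def power_tdt(
    n_informative: int,
    k: float,
    alpha: float,
    n_trials: int = 1000,
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo power of the pedigree transmission disequilibrium test.

    ``b ~ Binomial(n, k)`` transmissions of the favoured allele and
    ``c = n - b`` of the other; the McNemar statistic is referred to the
    chi-square(1) upper tail.
    """
    rng = np.random.default_rng(seed)
    b = rng.binomial(n_informative, k, size=n_trials)
    x = tdt_statistic(b, n_informative - b)
    pvals = stats.chi2.sf(x, df=1)
    power = float((pvals < alpha).mean())
    return PowerResult(n_informative, k, alpha, n_trials, power, "tdt_mcnemar")


@dataclass
class ExtremeTDReport:
    """Outcome of the end-to-end extreme-distortion power experiment."""

    result: PowerResult
    lead_pvalues: np.ndarray
    lead_fractions: np.ndarray
    causal_filtered_fraction: float
    n_failures: int


def power_extreme_td(
    profile: SimParams,
    n_reps: int = 20,
    alpha: float = 1.78e-7,
    seed: int = 0,
    hmm_params: HmmParams | None = None,
    stitch_mode: str = "lenient",
) -> ExtremeTDReport:
    """End-to-end power to detect extreme TD through the full pipeline.

    Each replicate simulates a distorted dataset (``profile.td_k``), runs
    phasing, imputation with superimposed observations and the binomial
    scan, and records the lead (minimum-p) observed hetSNP.  Power is the
    fraction of replicates whose lead p-value beats ``alpha``.  Pipeline
    failures are counted (as non-detections), never silently dropped, and
    the fraction of replicates whose causal SNP was filtered out as
    apparently homozygous is reported.

    Stitching defaults to lenient mode here: near the causal site the two
    haplotypes are carried at a ~99:1 ratio, which can leave window
    junctions with ambiguous consensus, and the distortion signal lives in
    the imputed genotypes, which are invariant to local haplotype-label
    flips.
    """
    if profile.td_k is None:
        raise ValueError("profile must set td_k")
    rng = np.random.default_rng(seed)
    lead_p, lead_f = [], []
    causal_filtered = 0
    failures = 0
    for _ in range(n_reps):
        params = replace(profile, seed=int(rng.integers(0, 2**31 - 1)))
        try:
            gm, truth = simulate_td_dataset(params)
            if not truth.causal_kept:
                causal_filtered += 1
            haps, _ = phase(gm, mode=stitch_mode)
            hp = hmm_params or HmmParams(
                n_hetsnps=gm.n_sites,
                genotyping_error=max(params.error_rate, 1e-4),
                avg_recomb=params.recomb_rate,
            )
            hp = replace(hp, n_hetsnps=gm.n_sites)
            imp = impute(gm, haps, hp, superimpose=True)
            scan = binomial_scan(imp)
            _, p, frac = scan.lead()
            lead_p.append(p)
            lead_f.append(max(frac, 1 - frac))
        except (DiscordantWindowsError, NoInformativeSitesError, ValueError) as exc:
            logger.warning("extreme-TD replicate failed: %s", exc)
            failures += 1
            lead_p.append(1.0)
            lead_f.append(float("nan"))
    lead_p_arr = np.asarray(lead_p)
    power = float((lead_p_arr < alpha).mean())
    result = PowerResult(profile.n_gametes, profile.td_k, alpha, n_reps, power, "pipeline_extreme")
    return ExtremeTDReport(
        result=result,
        lead_pvalues=lead_p_arr,
        lead_fractions=np.asarray(lead_f),
        causal_filtered_fraction=causal_filtered / n_reps,
        n_failures=failures,
    )
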