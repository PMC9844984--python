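"""Gamete genotype imputation by Viterbi decoding over phased haplotypes.

Each gamete chromosome is modelled as a two-state hidden Markov chain over
its observed, phased SNPs: the hidden state is the donor haplotype of origin
(H1 or H2), emissions are the observed alleles (correct with probability
1 - epsilon, flipped by genotyping error with probability epsilon), and a
state change between consecutive observed SNPs corresponds to a meiotic
crossover, with probability r / n_hetsnps (the expected number of crossovers
per chromosome spread uniformly over the hetSNPs).  Decoding is exact
(Viterbi, in log space) and runs independently per gamete.

After decoding, unobserved tracts flanked by a single haplotype are filled
with that haplotype; tracts between discordant flanks (crossover intervals)
stay NA, and chromosome-end tracts are filled from the nearest state unless
``fill_ends`` is disabled.  Optionally, original observations that conflict
with the inferred genotypes are superimposed back onto the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .matrix import NA, GameteMatrix
from .phasing import DonorHaplotypes

logger = logging.getLogger(__name__)

H1, H2 = np.int8(0), np.int8(1)

DEFAULT_GENOTYPING_ERROR = 0.005
DEFAULT_AVG_RECOMB = 1.0


@dataclass
class HmmParams:
    """Emission/transition parameters of the haplotype-of-origin HMM.

    ``genotyping_error`` is the per-observation probability that a genotype
    call is flipped; ``avg_recomb`` is the expected number of crossovers per
    chromosome per gamete.  The per-step transition probability is
    ``avg_recomb / n_hetsnps``, constant between consecutive observed SNPs.
    """

    n_hetsnps: int
    genotyping_error: float = DEFAULT_GENOTYPING_ERROR
    avg_recomb: float = DEFAULT_AVG_RECOMB

    def __post_init__(self) -> None:
        if not 0.0 < self.genotyping_error < 0.5:
            raise ValueError(f"genotyping_error must be in (0, 0.5), got {self.genotyping_error}")
        if self.n_hetsnps < 1:
            raise ValueError("n_hetsnps must be >= 1")
        if not 0.0 < self.p_trans < 0.5:
            raise ValueError(
                f"transition probability {self.p_trans} out of (0, 0.5); "
                "check avg_recomb relative to n_hetsnps"
            )

    @property
    def p_trans(self) -> float:
        return self.avg_recomb / self.n_hetsnps


@dataclass
class ImputedMatrix:
    """Dense per-gamete haplotype paths and genotypes after HMM + fill."""

    positions: np.ndarray
    gamete_ids: list[str]
    paths: np.ndarray  # int8 (sites x gametes) over {0=H1, 1=H2, -1=NA}
    genotypes: np.ndarray  # int8 over {0, 1, -1}
    filled: np.ndarray  # bool: path assigned by gap-filling, not decoding
    superimposed: bool = False
    observed_superimposed: np.ndarray | None = None  # bool where observation overrode inference

    @property
    def n_sites(self) -> int:
        return self.paths.shape[0]

    @property
    def n_gametes(self) -> int:
        return self.paths.shape[1]

    def completeness(self) -> np.ndarray:
        """Fraction of non-NA genotypes per gamete."""
        return (self.genotypes != NA).mean(axis=0)


def viterbi_decode(obs: np.ndarray, haps: DonorHaplotypes, params: HmmParams) -> np.ndarray:
    """Most likely haplotype state at each observed, phased site of one gamete.

    Returns a full-length int8 path with the decoded state at sites where the
    gamete has an observation and the phase is known, NA elsewhere.  Ties are
    broken toward no state change (fewer inferred crossovers); an exactly
    tied final state resolves to H1.
    """
    obs = np.asarray(obs, dtype=np.int8)
    if obs.shape != (haps.n_sites,):
        raise ValueError("observation vector length must match the phased positions")
    path = np.full(haps.n_sites, NA, dtype=np.int8)
    usable = (obs != NA) & (haps.h1 != NA)
    idx = np.flatnonzero(usable)
    if idx.size == 0:
        return path

    eps, p = params.genotyping_error, params.p_trans
    log_e = np.log([1.0 - eps, eps])  # [match, mismatch]
    log_stay, log_switch = np.log1p(-p), np.log(p)

    a = obs[idx]
    # emission log-likelihood per site for state H1 (allele h1) and H2 (1 - h1)
    match_h1 = (a == haps.h1[idx]).astype(np.intp)
    emit = np.empty((idx.size, 2))
    emit[:, 0] = log_e[1 - match_h1]
    emit[:, 1] = log_e[match_h1]

    n = idx.size
    v = np.log(0.5) + emit[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        for s in (0, 1):
            stay = v[s] + log_stay
            switch = v[1 - s] + log_switch
            # tie -> stay in the same state
            if stay >= switch:
                back[t, s] = s
                newscore = stay
            else:
                back[t, s] = 1 - s
                newscore = switch
            emitted = newscore + emit[t, s]
            if s == 0:
                nxt0 = emitted
            else:
                nxt1 = emitted
        v = np.array([nxt0, nxt1])
    state = 0 if v[0] >= v[1] else 1
    states = np.empty(n, dtype=np.int8)
    states[-1] = state
    for t in range(n - 1, 0, -1):
        state = back[t, state]
        states[t - 1] = state
    path[idx] = states
    return path


def path_log_probability(states: np.ndarray, obs: np.ndarray, haps: DonorHaplotypes, params: HmmParams) -> float:
    """Joint log-probability of a state path and the observations.

    Defined over the observed, phased sites only; used as the reference
    objective that :func:`viterbi_decode` maximises.
    """
    usable = (np.asarray(obs, dtype=np.int8) != NA) & (haps.h1 != NA)
    idx = np.flatnonzero(usable)
    states = np.asarray(states)
    if states.shape != idx.shape:
        raise ValueError("states must cover exactly the observed, phased sites")
    eps, p = params.genotyping_error, params.p_trans
    alleles = np.where(states == 0, haps.h1[idx], haps.h2[idx])
    match = alleles == np.asarray(obs, dtype=np.int8)[idx]
    lp = np.log(0.5)
    lp += float(np.where(match, np.log(1 - eps), np.log(eps)).sum())
    if len(states) > 1:
        changes = states[1:] != states[:-1]
        lp += float(np.where(changes, np.log(p), np.log1p(-p)).sum())
    return lp


def fill_unobserved(path: np.ndarray, fill_ends: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Fill NA runs in a sparse state path.

    Internal NA runs whose flanking states agree are filled with that state;
    runs between discordant flanks (crossover intervals) remain NA.  Terminal
    runs are filled from the nearest decoded state iff ``fill_ends``.
    Returns ``(dense_path, filled_mask)``.
    """
    path = np.asarray(path, dtype=np.int8)
    out = path.copy()
    idx = np.flatnonzero(path != NA)
    if idx.size == 0:
        return out, np.zeros_like(path, dtype=bool)
    pos = np.arange(len(path))
    # index of the nearest decoded site at or before / at or after each position
    right_rank = np.searchsorted(idx, pos, side="left")
    left_rank = np.searchsorted(idx, pos, side="right") - 1
    has_left = left_rank >= 0
    has_right = right_rank < idx.size
    left_state = np.where(has_left, path[idx[np.clip(left_rank, 0, idx.size - 1)]], NA)
    right_state = np.where(has_right, path[idx[np.clip(right_rank, 0, idx.size - 1)]], NA)

    na = path == NA
    interior = na & has_left & has_right & (left_state == right_state)
    out[interior] = left_state[interior]
    if fill_ends:
        lead = na & ~has_left
        trail = na & ~has_right
        out[lead] = right_state[lead]
        out[trail] = left_state[trail]
    filled = (out != NA) & na
    return out, filled


def impute(
    gm: GameteMatrix,
    haps: DonorHaplotypes,
    params: HmmParams | None = None,
    fill_ends: bool = True,
    superimpose: bool = True,
) -> ImputedMatrix:
    """Impute dense genotypes for every gamete.

    Runs Viterbi decoding and gap-filling per gamete, then translates the
    haplotype path into genotypes via the phased alleles (sites of unknown
    phase stay NA).  With ``superimpose`` enabled, conflicting original
    observations override the inferred genotypes (flagged per cell); disable
    it to obtain the smoothed matrix required for crossover discovery.
    """
    if params is None:
        params = HmmParams(n_hetsnps=gm.n_sites)
    if gm.n_sites != haps.n_sites:
        raise ValueError("gamete matrix and haplotypes cover different site sets")
    n_sites, n_gam = gm.genotypes.shape
    paths = np.full((n_sites, n_gam), NA, dtype=np.int8)
    filled = np.zeros((n_sites, n_gam), dtype=bool)
    for j in range(n_gam):
        sparse_path = viterbi_decode(gm.genotypes[:, j], haps, params)
        paths[:, j], filled[:, j] = fill_unobserved(sparse_path, fill_ends=fill_ends)

    genotypes = np.full((n_sites, n_gam), NA, dtype=np.int8)
    phased = haps.h1 != NA
    h1col = haps.h1[:, None]
    on_h1 = phased[:, None] & (paths == H1)
    on_h2 = phased[:, None] & (paths == H2)
    genotypes = np.where(on_h1, h1col, genotypes)
    genotypes = np.where(on_h2, 1 - h1col, genotypes).astype(np.int8)

    imp = ImputedMatrix(
        positions=gm.positions,
        gamete_ids=list(gm.gamete_ids),
        paths=paths,
        genotypes=genotypes,
        filled=filled,
    )
    if superimpose:
        imp = superimpose_observed(imp, gm)
    return imp


def superimpose_observed(imp: ImputedMatrix, gm: GameteMatrix, enable: bool = True) -> ImputedMatrix:
    """Overwrite inferred genotypes with conflicting original observations.

    Guards against over-smoothing by the HMM: wherever the raw data carries
    an allele that disagrees with (or is absent from) the imputed genotype,
    the observation wins and the cell is flagged.  With ``enable=False`` the
    input is returned unchanged.
    """
    if not enable:
        return imp
    observed = gm.genotypes != NA
    conflict = observed & (imp.genotypes != gm.genotypes)
    genotypes = np.where(conflict, gm.genotypes, imp.genotypes).astype(np.int8)
    n = int(conflict.sum())
    if n:
        logger.info("superimposed %d observed genotype(s) over inferred values", n)
    return replace(
        imp,
        genotypes=genotypes,
        superimposed=True,
        observed_superimposed=conflict,
    )
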