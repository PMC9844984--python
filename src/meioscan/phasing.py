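"""Reconstruction of the donor's two chromosome-scale haplotypes.

The default method works in overlapping windows of SNPs.  Within a window,
gametes are clustered into two groups by Ward agglomeration on pairwise
binary (Jaccard) distances; because each gamete carries one or the other
donor homolog over most of a window (crossovers being rare), the two
clusters correspond to the two haplotypes.  Per-cluster majority votes
decode the haplotype alleles, and the per-window haplotypes are stitched
left to right using the genotype consensus over the shared (overlap) SNPs.

The key assumption is that recombinant gametes are a minority within each
window, which favours windows that are large relative to the per-window
crossover probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.spatial.distance import squareform

from .matrix import NA, GameteMatrix

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_LENGTH = 3000
DEFAULT_STITCH_THRESHOLD = 0.9


class DiscordantWindowsError(RuntimeError):
    """Stringent stitching found a junction with ambiguous consensus."""


@dataclass
class WindowSpec:
    """Index ranges of overlapping SNP windows covering a chromosome."""

    window_length: int
    overlap: int
    bounds: list[tuple[int, int]]  # half-open [start, stop) index ranges

    @property
    def n_windows(self) -> int:
        return len(self.bounds)


@dataclass
class DonorHaplotypes:
    """Two complementary phased allele sequences over hetSNP positions."""

    positions: np.ndarray
    h1: np.ndarray  # int8 over {0, 1, -1}
    h2: np.ndarray

    def __post_init__(self) -> None:
        self.h1 = np.asarray(self.h1, dtype=np.int8)
        self.h2 = np.asarray(self.h2, dtype=np.int8)
        both = (self.h1 != NA) & (self.h2 != NA)
        if not np.array_equal(self.h2[both], 1 - self.h1[both]):
            raise ValueError("h2 must equal 1 - h1 wherever both are phased")

    @property
    def n_sites(self) -> int:
        return len(self.h1)

    @property
    def phased_fraction(self) -> float:
        if self.n_sites == 0:
            return 0.0
        return float((self.h1 != NA).mean())


@dataclass
class StitchReport:
    """Per-junction consensus values and the action taken."""

    consensus: list[float] = field(default_factory=list)
    action: list[str] = field(default_factory=list)  # keep / flip / error


def make_windows(n_snps: int, window_length: int = DEFAULT_WINDOW_LENGTH, overlap: int | None = None) -> WindowSpec:
    """Divide ``n_snps`` indices into overlapping windows.

    Consecutive windows share exactly ``overlap`` indices (default: half the
    window length); the final window is clipped at the chromosome end and may
    be shorter.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if overlap is None:
        overlap = window_length // 2
    if not (1 <= overlap < window_length):
        raise ValueError(f"overlap must satisfy 1 <= overlap < window_length, got {overlap}")
    if n_snps <= window_length:
        return WindowSpec(window_length, overlap, [(0, n_snps)])
    step = window_length - overlap
    bounds = []
    start = 0
    while True:
        stop = min(start + window_length, n_snps)
        bounds.append((start, stop))
        if stop == n_snps:
            break
        start += step
    return WindowSpec(window_length, overlap, bounds)


def jaccard_distances(genotypes: np.ndarray) -> np.ndarray:
    """Pairwise binary (Jaccard) distances between gamete columns.

    For a pair of gametes the distance is computed over pairwise-complete
    positions, treating allele 1 as "presence":
    ``d = (# discordant positions with >= 1 one) / (# positions with >= 1 one)``.
    Pairs with no such position are assigned distance 1 (kept maximally
    apart, as mutually uninformative).
    """
    obs = csr_matrix((genotypes != NA).astype(np.float64))
    ones = csr_matrix((genotypes == 1).astype(np.float64))
    n11 = (ones.T @ ones).toarray()
    ones_vs_obs = (ones.T @ obs).toarray()
    n10 = ones_vs_obs - n11  # this gamete 1, other observed 0
    num = n10 + n10.T
    den = n11 + num
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def _cluster_votes(genotypes: np.ndarray, members: np.ndarray) -> np.ndarray:
    """Per-site majority vote within one cluster; exact ties vote NA."""
    sub = genotypes[:, members]
    ones = (sub == 1).sum(axis=1)
    zeros = (sub == 0).sum(axis=1)
    votes = np.full(genotypes.shape[0], NA, dtype=np.int8)
    votes[ones > zeros] = 1
    votes[zeros > ones] = 0
    return votes


def phase_window(genotypes: np.ndarray) -> np.ndarray:
    """Phase one window; returns the window's haplotype-1 calls ({0,1,-1}).

    Steps: Jaccard distances, Ward (D2 update) agglomeration cut into two
    clusters, per-cluster majority voting, then reconciliation of the two
    cluster votes: complementary votes are accepted, a one-sided NA is filled
    as the complement of the other cluster's vote, and contradictory votes
    (both clusters voting the same allele) become NA.
    """
    n_sites, n_gam = genotypes.shape
    if n_gam < 2:
        return np.full(n_sites, NA, dtype=np.int8)
    d = jaccard_distances(genotypes)
    z = linkage(squareform(d, checks=False), method="ward")
    labels = fcluster(z, t=2, criterion="maxclust")
    members1 = np.flatnonzero(labels == 1)
    members2 = np.flatnonzero(labels == 2)
    if members1.size == 0 or members2.size == 0:
        # degenerate window (e.g. all gametes identical): no second cluster
        logger.warning("degenerate window: tree cut produced a single cluster; phasing as NA")
        return np.full(n_sites, NA, dtype=np.int8)
    v1 = _cluster_votes(genotypes, members1)
    v2 = _cluster_votes(genotypes, members2)

    h = np.full(n_sites, NA, dtype=np.int8)
    only1 = (v1 != NA) & (v2 == NA)
    only2 = (v1 == NA) & (v2 != NA)
    both = (v1 != NA) & (v2 != NA)
    h[only1] = v1[only1]
    h[only2] = 1 - v2[only2]
    agree = both & (v2 == 1 - v1)  # complementary clusters
    h[agree] = v1[agree]
    # contradictory (v1 == v2): left as NA
    return h


def stitch_haplotypes(
    window_haps: list[np.ndarray],
    spec: WindowSpec,
    positions: np.ndarray,
    threshold: float = DEFAULT_STITCH_THRESHOLD,
    mode: str = "stringent",
) -> tuple[DonorHaplotypes, StitchReport]:
    """Stitch per-window haplotypes into chromosome-scale haplotypes.

    Walking left to right, each window is kept or allele-flipped to align
    with the growing haplotype 1.  The consensus at a junction is the match
    fraction over overlap sites phased in both the growing haplotype and the
    new window.  In stringent mode a consensus inside
    ``[1 - threshold, threshold]`` (or an empty comparable overlap) raises
    :class:`DiscordantWindowsError`; lenient mode picks the orientation with
    the higher consensus, keeping the current orientation on an exact tie.
    At overlap sites the left window's call wins unless it is NA.
    """
    if mode not in ("stringent", "lenient"):
        raise ValueError(f"unknown stitch mode {mode!r}")
    if not window_haps:
        raise ValueError("need at least one window")
    n_snps = spec.bounds[-1][1]
    h1 = np.full(n_snps, NA, dtype=np.int8)
    report = StitchReport()

    start0, stop0 = spec.bounds[0]
    h1[start0:stop0] = window_haps[0]
    for w in range(1, len(window_haps)):
        start, stop = spec.bounds[w]
        cur = window_haps[w].copy()
        prev_stop = spec.bounds[w - 1][1]
        ov_lo, ov_hi = start, prev_stop
        left = h1[ov_lo:ov_hi]
        right = cur[: ov_hi - ov_lo]
        comparable = (left != NA) & (right != NA)
        n_cmp = int(comparable.sum())
        if n_cmp == 0:
            if mode == "stringent":
                report.consensus.append(np.nan)
                report.action.append("error")
                raise DiscordantWindowsError(
                    f"no comparable overlap sites at junction {w} (windows {w - 1}/{w})"
                )
            logger.warning("junction %d: no comparable overlap sites; keeping orientation", w)
            consensus, action = np.nan, "keep"
        else:
            consensus = float((left[comparable] == right[comparable]).mean())
            if consensus > threshold:
                action = "keep"
            elif consensus < 1.0 - threshold:
                action = "flip"
            elif mode == "stringent":
                report.consensus.append(consensus)
                report.action.append("error")
                raise DiscordantWindowsError(
                    f"discordant windows at junction {w} (windows {w - 1}/{w}): "
                    f"consensus {consensus:.3f} within [{1 - threshold:.3f}, {threshold:.3f}]"
                )
            else:  # lenient: highest-consensus orientation, tie -> keep
                action = "keep" if consensus >= 0.5 else "flip"
                logger.info(
                    "junction %d: lenient stitch with consensus %.3f -> %s", w, consensus, action
                )
        if action == "flip":
            phased = cur != NA
            cur[phased] = 1 - cur[phased]
        report.consensus.append(consensus)
        report.action.append(action)
        fill = h1[start:stop] == NA
        h1[start:stop][fill] = cur[fill]

    h2 = np.where(h1 == NA, NA, 1 - h1).astype(np.int8)
    return DonorHaplotypes(positions=positions, h1=h1, h2=h2), report


def phase(
    gm: GameteMatrix,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    overlap: int | None = None,
    threshold: float = DEFAULT_STITCH_THRESHOLD,
    mode: str = "stringent",
) -> tuple[DonorHaplotypes, StitchReport]:
    """Phase a gamete matrix with the windowed clustering method."""
    spec = make_windows(gm.n_sites, window_length=window_length, overlap=overlap)
    window_haps = [phase_window(gm.genotypes[start:stop]) for start, stop in spec.bounds]
    return stitch_haplotypes(window_haps, spec, gm.positions, threshold=threshold, mode=mode)
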