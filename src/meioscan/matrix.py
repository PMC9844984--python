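"""Sparse gamete genotype matrices: loading, encoding, and site filtering.

The central container is :class:`GameteMatrix`, a SNPs x gametes table of
genotype observations from low-coverage sequencing of individual gametes
(sperm or oocytes) from a single diploid donor, restricted to one chromosome.
Genotypes are coded 0 (reference allele), 1 (alternative allele) and NA
(unobserved), with NA stored as -1 in an int8 array.

Only SNPs heterozygous in the donor are informative for phasing and for
transmission-distortion testing, so the canonical preprocessing keeps sites
where both alleles were seen at least once across the gamete pool.  Two
additional filters mitigate alignment artifacts in real data: exclusion of
technically challenging regions supplied as BED files, and removal of sites
with an excess of genotype observations (suggestive of donor-specific
segmental duplications, which pile up reads from both copies at one locus).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype in int8 genotype arrays.
NA = np.int8(-1)

_NUCLEOTIDES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


class NoInformativeSitesError(ValueError):
    """Raised when filtering leaves no informative hetSNPs."""


@dataclass
class GameteMatrix:
    """Sparse SNP x gamete genotype observations on one chromosome.

    Parameters
    ----------
    positions
        1-based genomic coordinates, strictly increasing, one per SNP row.
    gamete_ids
        Column labels, one per gamete cell.
    genotypes
        ``(n_sites, n_gametes)`` int8 array over {0, 1, -1} where -1 is NA.
    ref_allele, alt_allele
        Optional per-site nucleotides (only populated for nucleotide input).
    chrom
        Chromosome name used when intersecting with BED intervals.
    """

    positions: np.ndarray
    gamete_ids: list[str]
    genotypes: np.ndarray
    ref_allele: np.ndarray | None = None
    alt_allele: np.ndarray | None = None
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-dimensional (sites x gametes)")
        if self.genotypes.shape != (len(self.positions), len(self.gamete_ids)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} inconsistent with "
                f"{len(self.positions)} positions x {len(self.gamete_ids)} gametes"
            )
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.genotypes, (0, 1, NA))
        if bad.any():
            raise ValueError("genotypes must be coded 0, 1 or -1 (NA)")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_gametes(self) -> int:
        return self.genotypes.shape[1]

    def observation_counts(self) -> np.ndarray:
        """Number of non-NA genotype calls per site."""
        return (self.genotypes != NA).sum(axis=1)

    def take_sites(self, index: np.ndarray) -> "GameteMatrix":
        """Row-subset preserving gametes and per-site alleles."""
        return replace(
            self,
            positions=self.positions[index],
            genotypes=self.genotypes[index],
            ref_allele=None if self.ref_allele is None else self.ref_allele[index],
            alt_allele=None if self.alt_allele is None else self.alt_allele[index],
        )


@dataclass
class SiteFilterReport:
    """Accounting of sites removed by the preprocessing filters."""

    n_input_sites: int
    n_dropped_non_het: int = 0
    n_dropped_excess: int = 0
    n_dropped_bed: int = 0
    observation_counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    @property
    def n_retained(self) -> int:
        return (
            self.n_input_sites
            - self.n_dropped_non_het
            - self.n_dropped_excess
            - self.n_dropped_bed
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": [
                    self.n_input_sites,
                    self.n_dropped_non_het,
                    self.n_dropped_excess,
                    self.n_dropped_bed,
                    self.n_retained,
                ]
            },
            index=["input", "dropped_non_het", "dropped_excess", "dropped_bed", "retained"],
        )


def load_gamete_table(path: str | Path, encoding: str = "binary", chrom: str = "chr1") -> GameteMatrix:
    """Read a tab-delimited gamete genotype table.

    The table must carry a ``pos`` column followed by one column per gamete;
    nucleotide encoding additionally requires ``ref`` and ``alt`` columns.
    Missing values are spelled ``NA``.  Nucleotide calls matching neither the
    ref nor the alt allele at their site are set to NA with a warning, since
    they most plausibly reflect genotyping error, which the downstream model
    absorbs.  Rows are sorted by ascending position.
    """
    if encoding not in ("binary", "nucleotide"):
        raise ValueError(f"unknown encoding {encoding!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if "pos" not in df.columns:
        raise FormatError(f"{path}: missing required 'pos' column")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    if pos.isna().any():
        raise FormatError(f"{path}: non-numeric entry in 'pos' column")
    pos = pos.astype(np.int64)
    dup = pos[pos.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate position {int(dup.iloc[0])}")

    meta_cols = {"pos"}
    ref = alt = None
    if encoding == "nucleotide":
        for col in ("ref", "alt"):
            if col not in df.columns:
                raise FormatError(f"{path}: nucleotide encoding requires a '{col}' column")
        meta_cols |= {"ref", "alt"}
        ref = df["ref"].str.upper().to_numpy()
        alt = df["alt"].str.upper().to_numpy()
    gamete_ids = [c for c in df.columns if c not in meta_cols]
    if not gamete_ids:
        raise FormatError(f"{path}: no gamete columns found")

    raw = df[gamete_ids].to_numpy()
    geno = np.full(raw.shape, NA, dtype=np.int8)
    if encoding == "binary":
        geno[raw == "0"] = 0
        geno[raw == "1"] = 1
        unexpected = ~((raw == "0") | (raw == "1") | (raw == "NA") | (raw == ""))
        if unexpected.any():
            raise FormatError(f"{path}: unexpected value {raw[unexpected][0]!r} in binary table")
    else:
        upper = np.char.upper(raw.astype(str))
        geno[upper == ref[:, None]] = 0
        geno[upper == alt[:, None]] = 1
        observed = (upper != "NA") & (upper != "")
        mismatched = observed & (geno == NA)
        if mismatched.any():
            n_bad = int(mismatched.sum())
            logger.warning(
                "%s: %d nucleotide call(s) matched neither ref nor alt; set to NA", path, n_bad
            )

    order = np.argsort(pos.to_numpy(), kind="stable")
    gm = GameteMatrix(
        positions=pos.to_numpy()[order],
        gamete_ids=gamete_ids,
        genotypes=geno[order],
        ref_allele=None if ref is None else ref[order],
        alt_allele=None if alt is None else alt[order],
        chrom=chrom,
    )
    return gm


def write_gamete_table(gm: GameteMatrix, path: str | Path, header_comment: str | None = None) -> None:
    """Write a :class:`GameteMatrix` in the same TSV dialect read by
    :func:`load_gamete_table` (binary encoding, NA spelled ``NA``)."""
    data: dict[str, object] = {"pos": gm.positions}
    if gm.ref_allele is not None and gm.alt_allele is not None:
        data["ref"] = gm.ref_allele
        data["alt"] = gm.alt_allele
    geno = gm.genotypes.astype(object)
    for j, gid in enumerate(gm.gamete_ids):
        col = geno[:, j]
        col = np.where(col == -1, "NA", col)
        data[gid] = col
    frame = pd.DataFrame(data)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def filter_to_informative_hetsnps(gm: GameteMatrix) -> tuple[GameteMatrix, SiteFilterReport]:
    """Keep sites with at least one observed 0 and one observed 1.

    Sites where only a single allele was seen across all gametes are
    uninformative: they are indistinguishable from homozygous positions in
    the donor.  Raises :class:`NoInformativeSitesError` when nothing remains.
    """
    has0 = (gm.genotypes == 0).any(axis=1)
    has1 = (gm.genotypes == 1).any(axis=1)
    keep = has0 & has1
    report = SiteFilterReport(
        n_input_sites=gm.n_sites,
        n_dropped_non_het=int((~keep).sum()),
        observation_counts=gm.observation_counts(),
    )
    if not keep.any():
        raise NoInformativeSitesError("no informative hetSNPs remain after filtering")
    return gm.take_sites(np.flatnonzero(keep)), report


def filter_excess_observation_sites(gm: GameteMatrix, n_sd: float = 1.0) -> tuple[GameteMatrix, SiteFilterReport]:
    """Drop sites whose observation count exceeds mean + ``n_sd`` * sd.

    The mean and (sample) standard deviation are computed on the input matrix,
    i.e. per donor and chromosome.  Sites covered in unusually many cells are
    suspect for donor-specific segmental duplications, which can mimic
    transmission distortion.
    """
    if gm.n_sites < 2:
        raise ValueError("excess-observation filter needs at least 2 sites")
    counts = gm.observation_counts()
    mean = counts.mean()
    sd = counts.std(ddof=1)
    threshold = mean + n_sd * sd
    keep = counts <= threshold
    report = SiteFilterReport(
        n_input_sites=gm.n_sites,
        n_dropped_excess=int((~keep).sum()),
        observation_counts=counts,
    )
    return gm.take_sites(np.flatnonzero(keep)), report


def read_bed3(path: str | Path) -> list[tuple[str, int, int]]:
    """Parse a BED3 file into (chrom, start, end) tuples."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinate") from exc
            intervals.append((fields[0], start, end))
    return intervals


def exclude_bed_regions(gm: GameteMatrix, beds: Iterable[str | Path]) -> tuple[GameteMatrix, SiteFilterReport]:
    """Remove sites falling inside any interval of the given BED files.

    A site with position ``p`` is excluded when ``start <= p < end`` for an
    interval on the matrix's chromosome.
    """
    drop = np.zeros(gm.n_sites, dtype=bool)
    for bed in beds:
        for chrom, start, end in read_bed3(bed):
            if chrom != gm.chrom:
                continue
            drop |= (gm.positions >= start) & (gm.positions < end)
    report = SiteFilterReport(
        n_input_sites=gm.n_sites,
        n_dropped_bed=int(drop.sum()),
        observation_counts=gm.observation_counts(),
    )
    return gm.take_sites(np.flatnonzero(~drop)), report


def filter_to_keeplist(gm: GameteMatrix, positions: Sequence[int] | str | Path) -> tuple[GameteMatrix, SiteFilterReport]:
    """Restrict to a list of known SNP positions (e.g. a reference panel).

    ``positions`` may be a sequence of integers or a path to a plain text
    file with one position per line.
    """
    if isinstance(positions, (str, Path)):
        keep_pos = np.loadtxt(positions, dtype=np.int64, ndmin=1)
    else:
        keep_pos = np.asarray(list(positions), dtype=np.int64)
    keep = np.isin(gm.positions, keep_pos)
    report = SiteFilterReport(
        n_input_sites=gm.n_sites,
        n_dropped_bed=0,
        observation_counts=gm.observation_counts(),
    )
    report.n_dropped_non_het = 0
    report.n_dropped_excess = 0
    # keep-list removals are tracked separately from the named counters
    return gm.take_sites(np.flatnonzero(keep)), report


def preprocess(
    gm: GameteMatrix,
    beds: Iterable[str | Path] = (),
    keeplist: Sequence[int] | str | Path | None = None,
    excess_n_sd: float | None = 1.0,
) -> tuple[GameteMatrix, list[SiteFilterReport]]:
    """Apply the canonical filter chain in its pinned order.

    Order: BED exclusion -> keep-list subset -> excess-observation filter ->
    informative-hetSNP filter.  The order only matters through the mean/sd of
    the excess filter, which must be computed before uninformative sites are
    removed.
    """
    reports = []
    if beds:
        gm, rep = exclude_bed_regions(gm, beds)
        reports.append(rep)
    if keeplist is not None:
        gm, rep = filter_to_keeplist(gm, keeplist)
        reports.append(rep)
    if excess_n_sd is not None and not math.isinf(excess_n_sd) and gm.n_sites >= 2:
        gm, rep = filter_excess_observation_sites(gm, n_sd=excess_n_sd)
        reports.append(rep)
    gm, rep = filter_to_informative_hetsnps(gm)
    reports.append(rep)
    return gm, reports
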