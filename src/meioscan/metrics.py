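"""Truth-aware benchmarking metrics for phasing, imputation and crossovers.

Sequence metrics operate on pairs of {0,1,NA} vectors: accuracy is one minus
the Hamming error rate, where a position with an NA in either sequence is
not a mismatch but still counts in the denominator; completeness is the
non-NA fraction; the switch error rate counts NA-uninterrupted stretches of
adjacent mismatches (one switch per stretch); the largest segment is the
longest NA-free run of matches.  Haplotype-level evaluation tries both truth
orientations (the phaser's H1/H2 labels are arbitrary) and keeps the better.

Crossover discovery is scored as a per-gamete classification problem: a
simulated breakpoint matched by a predicted interval containing it is a TP
(greedy one-to-one matching in genomic order), an unmatched prediction a FP,
an unmatched truth a FN, and a chromosome with neither truth nor prediction
a TN.  Counts are pooled across gametes before ratios are formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import NA
from .crossover import BreakpointInterval
from .imputation import ImputedMatrix
from .phasing import DonorHaplotypes
from .simulate import SimTruth


@dataclass
class SeqMetrics:
    accuracy: float
    completeness: float
    switch_error_rate: float
    largest_segment_fraction: float


@dataclass
class DiscoveryMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    tpr: float
    fdr: float
    precision: float
    f1: float
    fpr: float
    tnr: float
    accuracy: float
    mean_resolution: float
    median_resolution: float


def _check_lengths(inferred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(inferred, dtype=np.int8)
    b = np.asarray(truth, dtype=np.int8)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("sequences must be 1-D and of equal length")
    return a, b


def seq_accuracy_completeness(inferred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(accuracy, completeness) of an inferred sequence against truth."""
    a, b = _check_lengths(inferred, truth)
    n = a.size
    if n == 0:
        raise ValueError("empty sequences")
    mismatch = (a != b) & (a != NA) & (b != NA)
    accuracy = 1.0 - mismatch.sum() / n
    completeness = float((a != NA).mean())
    return float(accuracy), completeness


def switch_error_rate(inferred: np.ndarray, truth: np.ndarray) -> float:
    """Switches per position: first mismatches of NA-uninterrupted stretches."""
    a, b = _check_lengths(inferred, truth)
    n = a.size
    usable = (a != NA) & (b != NA)
    mismatch = usable & (a != b)
    # a mismatch starts a stretch when the previous position was not a
    # mismatch continuing the same stretch (an NA in either sequence breaks it)
    prev_mismatch = np.zeros(n, dtype=bool)
    prev_mismatch[1:] = mismatch[:-1]
    starts = mismatch & ~prev_mismatch
    return float(starts.sum() / n)


def largest_segment(inferred: np.ndarray, truth: np.ndarray) -> tuple[int, float]:
    """Longest NA-free run of adjacent matches, and its fraction of length."""
    a, b = _check_lengths(inferred, truth)
    match = (a == b) & (a != NA) & (b != NA)
    best = run = 0
    for m in match:
        run = run + 1 if m else 0
        if run > best:
            best = run
    return best, best / a.size if a.size else 0.0


def best_orientation(haps: DonorHaplotypes, truth_h1: np.ndarray) -> np.ndarray:
    """The truth haplotype (h1 or its complement) best matching inferred h1."""
    truth_h1 = np.asarray(truth_h1, dtype=np.int8)
    acc_direct, _ = seq_accuracy_completeness(haps.h1, truth_h1)
    acc_flipped, _ = seq_accuracy_completeness(haps.h1, (1 - truth_h1).astype(np.int8))
    return truth_h1 if acc_direct >= acc_flipped else (1 - truth_h1).astype(np.int8)


def evaluate_phasing(haps: DonorHaplotypes, truth: SimTruth) -> SeqMetrics:
    """Score phased haplotypes against simulated truth (best orientation)."""
    truth_h1 = truth.h1[truth.kept_sites]
    ref = best_orientation(haps, truth_h1)
    acc, comp = seq_accuracy_completeness(haps.h1, ref)
    ser = switch_error_rate(haps.h1, ref)
    _, seg = largest_segment(haps.h1, ref)
    return SeqMetrics(acc, comp, ser, seg)


def evaluate_imputation(imp: ImputedMatrix, truth: SimTruth) -> SeqMetrics:
    """Score imputed gamete genotypes against truth, averaged over gametes."""
    truth_geno = truth.genotypes[truth.kept_sites]
    if truth_geno.shape != imp.genotypes.shape:
        raise ValueError("imputed matrix and truth cover different site sets")
    accs, comps, sers, segs = [], [], [], []
    for j in range(imp.n_gametes):
        acc, comp = seq_accuracy_completeness(imp.genotypes[:, j], truth_geno[:, j])
        accs.append(acc)
        comps.append(comp)
        sers.append(switch_error_rate(imp.genotypes[:, j], truth_geno[:, j]))
        segs.append(largest_segment(imp.genotypes[:, j], truth_geno[:, j])[1])
    return SeqMetrics(
        float(np.mean(accs)), float(np.mean(comps)), float(np.mean(sers)), float(np.mean(segs))
    )


def classify_breakpoints(
    predicted: list[BreakpointInterval],
    truth_gaps: np.ndarray,
    truth_positions: np.ndarray,
) -> tuple[int, int, int, int]:
    """(tp, tn, fp, fn) for one gamete chromosome.

    ``truth_gaps`` are the simulated crossover gap indices on the underlying
    site grid (gap ``i`` lies between ``truth_positions[i]`` and
    ``truth_positions[i+1]``).  A predicted interval matches a truth gap when
    the gap's midpoint lies strictly inside the interval; matching is greedy,
    one-to-one, in genomic order.
    """
    truth_gaps = np.sort(np.asarray(truth_gaps, dtype=np.int64))
    mids = (
        truth_positions[truth_gaps].astype(np.float64)
        + truth_positions[truth_gaps + 1].astype(np.float64)
    ) / 2.0
    preds = sorted(predicted, key=lambda bp: (bp.start_pos, bp.end_pos))
    if truth_gaps.size == 0 and not preds:
        return 0, 1, 0, 0
    tp = 0
    t = 0
    for bp in preds:
        while t < mids.size and mids[t] <= bp.start_pos:
            t += 1  # truth gap lies at/before the interval start: unmatched -> FN
        if t < mids.size and bp.start_pos < mids[t] < bp.end_pos:
            tp += 1
            t += 1
    fp = len(preds) - tp
    fn = int(truth_gaps.size) - tp
    return tp, 0, fp, fn


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def discovery_summary(
    classifications: list[tuple[int, int, int, int]],
    resolutions: list[int] | None = None,
) -> DiscoveryMetrics:
    """Pool per-gamete (tp, tn, fp, fn) counts and form the ratio metrics.

    Ratios with zero denominators are reported as NaN (no prediction class).
    """
    if not classifications:
        raise ValueError("need at least one gamete classification")
    arr = np.asarray(classifications, dtype=np.int64)
    tp, tn, fp, fn = (int(x) for x in arr.sum(axis=0))
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    res = np.asarray(resolutions if resolutions else [], dtype=np.float64)
    return DiscoveryMetrics(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        tpr=recall,
        fdr=_ratio(fp, tp + fp),
        precision=precision,
        f1=f1,
        fpr=_ratio(fp, tn + fp),
        tnr=_ratio(tn, tn + fp),
        accuracy=_ratio(tp + tn, tp + tn + fp + fn),
        mean_resolution=float(res.mean()) if res.size else float("nan"),
        median_resolution=float(np.median(res)) if res.size else float("nan"),
    )


def evaluate_crossovers(
    calls: dict[str, list[BreakpointInterval]],
    truth: SimTruth,
) -> DiscoveryMetrics:
    """Score crossover calls for all gametes against simulated breakpoints."""
    classifications = []
    resolutions: list[int] = []
    gamete_index = {gid: j for j, gid in enumerate(calls.keys())}
    for gid, preds in calls.items():
        j = gamete_index[gid]
        classifications.append(
            classify_breakpoints(preds, truth.breakpoints[j], truth.positions)
        )
        resolutions.extend(bp.resolution for bp in preds)
    return discovery_summary(classifications, resolutions)
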