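"""End-to-end orchestration of the three-stage gamete analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crossover import BreakpointInterval, discover_crossovers
from .imputation import HmmParams, ImputedMatrix, impute, superimpose_observed
from .matrix import GameteMatrix
from .phasing import (
    DEFAULT_STITCH_THRESHOLD,
    DEFAULT_WINDOW_LENGTH,
    DonorHaplotypes,
    StitchReport,
    phase,
)


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with the package defaults."""

    window_length: int = DEFAULT_WINDOW_LENGTH
    overlap: int | None = None  # None: half the window length
    stitch_threshold: float = DEFAULT_STITCH_THRESHOLD
    stitch_mode: str = "stringent"
    genotyping_error: float = 0.005
    avg_recomb: float = 1.0
    fill_ends: bool = True
    smooth_imputed_genotypes: bool = True  # keep a smoothed matrix for crossovers
    seed: int = 0

    def hmm_params(self, n_hetsnps: int) -> HmmParams:
        return HmmParams(
            n_hetsnps=n_hetsnps,
            genotyping_error=self.genotyping_error,
            avg_recomb=self.avg_recomb,
        )


@dataclass
class PipelineResult:
    """Artifacts of a full phasing / imputation / crossover run."""

    haplotypes: DonorHaplotypes
    stitch_report: StitchReport
    imputed: ImputedMatrix  # final matrix, observations superimposed
    smoothed: ImputedMatrix  # HMM output without superimposition
    crossovers: dict[str, list[BreakpointInterval]]

    def crossover_counts(self) -> np.ndarray:
        return np.array([len(v) for v in self.crossovers.values()])


def run_pipeline(gm: GameteMatrix, config: RunConfig | None = None) -> PipelineResult:
    """Phase the donor, impute every gamete, and call crossovers.

    Crossover discovery always runs on the smoothed (non-superimposed)
    matrix; the returned ``imputed`` matrix carries the superimposed
    observations for downstream transmission tests.
    """
    config = config or RunConfig()
    haps, stitch_report = phase(
        gm,
        window_length=config.window_length,
        overlap=config.overlap,
        threshold=config.stitch_threshold,
        mode=config.stitch_mode,
    )
    params = config.hmm_params(gm.n_sites)
    smoothed = impute(gm, haps, params, fill_ends=config.fill_ends, superimpose=False)
    crossovers = discover_crossovers(smoothed)
    final = superimpose_observed(smoothed, gm)
    return PipelineResult(
        haplotypes=haps,
        stitch_report=stitch_report,
        imputed=final,
        smoothed=smoothed,
        crossovers=crossovers,
    )
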