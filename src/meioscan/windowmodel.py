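"""Automatic phasing window-size selection via beta regression.

The optimal phasing window length trades off two pressures: larger windows
pool more gamete observations per clustering problem (helping at low
coverage or small sample sizes), while recombinant gametes — whose in-window
haplotype switches pollute the clusters — become more numerous as windows
grow.  The model captures this empirically: small datasets are simulated
over a grid of study designs, the window proportion (window length / SNP
count) maximising phasing accuracy is recorded for each (ties prefer the
larger window), and a beta regression with a logit mean link is fitted with
the optimal proportion as the response and gamete count, coverage,
genotyping error rate and recombination rate as predictors.  Because the
mean link is monotone, each fitted coefficient's sign directly determines
whether the recommended proportion grows or shrinks with that input.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.othermod.betareg import BetaModel

from .matrix import NoInformativeSitesError
from .metrics import evaluate_phasing
from .phasing import DEFAULT_WINDOW_LENGTH, phase
from .simulate import SimParams, simulate_dataset

logger = logging.getLogger(__name__)

PREDICTORS = ("n_gametes", "coverage", "error_rate", "recomb_rate")

DEFAULT_PROPORTIONS = (0.05, 0.1, 0.2, 0.35, 0.6, 0.9)

DEFAULT_GRID = {
    "n_gametes": (20, 60, 150),
    "coverage": (0.15, 0.4, 1.0),
    "error_rate": (0.005, 0.03),
    "recomb_rate": (0.5, 1.5, 4.0),
}
DEFAULT_GRID_SNPS = 600


@dataclass
class WindowSizeModel:
    """Fitted beta regression mapping study design to window proportion."""

    params: pd.Series
    hull: dict[str, tuple[float, float]]  # training min/max per predictor
    training: pd.DataFrame = field(repr=False, default=None)

    def coefficient(self, name: str) -> float:
        return float(self.params[name])

    def predict_proportion(
        self,
        n_gametes: float,
        coverage: float,
        error_rate: float,
        recomb_rate: float,
    ) -> float:
        """Predicted optimal window proportion, in (0, 1).

        Inputs outside the training grid's hull are clamped to it (with a
        warning): the regression is only trusted as an interpolator.
        """
        values = {
            "n_gametes": n_gametes,
            "coverage": coverage,
            "error_rate": error_rate,
            "recomb_rate": recomb_rate,
        }
        eta = float(self.params["const"])
        for name in PREDICTORS:
            lo, hi = self.hull[name]
            v = values[name]
            if not lo <= v <= hi:
                clamped = min(max(v, lo), hi)
                logger.warning(
                    "window model: %s=%g outside training hull [%g, %g]; clamped",
                    name, v, lo, hi,
                )
                v = clamped
            eta += float(self.params[name]) * v
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_window_length(self, n_snps: int, **kwargs: float) -> int:
        prop = self.predict_proportion(**kwargs)
        return max(2, int(round(prop * n_snps)))


def optimal_window_proportion(
    p: SimParams,
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS,
) -> float | None:
    """Best window proportion for one simulated dataset (ties -> larger)."""
    try:
        gm, truth = simulate_dataset(p)
    except NoInformativeSitesError:
        return None
    best_prop, best_acc = None, -np.inf
    for prop in proportions:
        window = max(2, int(round(prop * gm.n_sites)))
        overlap = max(1, window // 2)
        try:
            haps, _ = phase(gm, window_length=window, overlap=overlap, mode="lenient")
        except ValueError:
            continue
        acc = evaluate_phasing(haps, truth).accuracy
        if acc >= best_acc:  # ties prefer the larger proportion
            best_acc, best_prop = acc, prop
    return best_prop


def build_training_grid(
    seed: int = 0,
    grid: dict[str, tuple[float, ...]] | None = None,
    n_snps: int = DEFAULT_GRID_SNPS,
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS,
) -> pd.DataFrame:
    """Simulate the training grid and record per-design optimal proportions."""
    grid = grid or DEFAULT_GRID
    rng = np.random.default_rng(seed)
    rows = []
    for n_gam, cov, err, rec in itertools.product(
        grid["n_gametes"], grid["coverage"], grid["error_rate"], grid["recomb_rate"]
    ):
        p = SimParams(
            n_gametes=int(n_gam),
            n_hetsnps=n_snps,
            coverage=float(cov),
            error_rate=float(err),
            recomb_rate=float(rec),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        opt = optimal_window_proportion(p, proportions)
        if opt is None:
            continue
        rows.append(
            {
                "n_gametes": n_gam,
                "coverage": cov,
                "error_rate": err,
                "recomb_rate": rec,
                "optimal_proportion": opt,
            }
        )
    return pd.DataFrame(rows)


def fit_window_model(
    seed: int = 0,
    training: pd.DataFrame | None = None,
    **grid_kwargs,
) -> WindowSizeModel:
    """Fit the beta regression on a (freshly simulated) training grid."""
    if training is None:
        training = build_training_grid(seed=seed, **grid_kwargs)
    if len(training) < len(PREDICTORS) + 2:
        raise ValueError("training grid too small to fit the window model")
    y = training["optimal_proportion"].to_numpy(dtype=float)
    # squeeze exact 0/1 responses into the open interval, the standard
    # continuity correction for beta-distributed responses
    n = y.size
    y = (y * (n - 1) + 0.5) / n
    exog = training[list(PREDICTORS)].astype(float)
    exog.insert(0, "const", 1.0)
    fit = BetaModel(y, exog).fit(disp=False)
    hull = {
        name: (float(training[name].min()), float(training[name].max()))
        for name in PREDICTORS
    }
    return WindowSizeModel(params=fit.params[exog.columns], hull=hull, training=training)


def auto_window_length(
    n_snps: int,
    n_gametes: float,
    coverage: float,
    error_rate: float,
    recomb_rate: float,
    model: WindowSizeModel | None = None,
) -> int:
    """Window length recommendation; falls back to the fixed default."""
    if model is None:
        logger.warning(
            "no fitted window model available; falling back to the default window length %d",
            DEFAULT_WINDOW_LENGTH,
        )
        return min(DEFAULT_WINDOW_LENGTH, max(2, n_snps))
    return model.predict_window_length(
        n_snps,
        n_gametes=n_gametes,
        coverage=coverage,
        error_rate=error_rate,
        recomb_rate=recomb_rate,
    )
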