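"""Model comparison: deviance information criterion and spatial fraction.

DIC = Dbar + pD, where Dbar is the posterior mean of the deviance
D(theta) = -2 log p(y | theta) and pD = Dbar - D(theta_hat) with theta_hat
the componentwise posterior mean of all parameters, random effects
included (conditional DIC).  The spatial fraction
SF = sigma_u^2 / (sigma_u^2 + sigma_v^2) measures how much of the
unexplained area-level variance is spatially structured; SF near 1 means
the spatially dependent effect dominates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DesignMatrices, MultilevelDataset, encode_design
from .inference import McmcSettings, PosteriorDraws, fit
from .model_core import ModelSpec, linear_predictor, log_likelihood
from .spatial_graph import AreaGraph

logger = logging.getLogger(__name__)

__all__ = ["FitComparison", "dic", "spatial_fraction", "compare"]


@dataclass
class FitComparison:
    """Per-variant DIC components (and SF for the spatial variant)."""

    table: pd.DataFrame
    draws: dict[str, PosteriorDraws] = field(default_factory=dict)

    @property
    def best_variant(self) -> str:
        return str(self.table["DIC"].idxmin())


def dic(
    draws: PosteriorDraws,
    ds: MultilevelDataset,
    spec: ModelSpec,
    design: DesignMatrices | None = None,
    area_schema=None,
    min_draws: int = 200,
) -> tuple[float, float, float]:
    """Return (DIC, Dbar, pD).

    The plug-in deviance is evaluated at the componentwise posterior mean of
    every parameter including u and v.  Slightly negative pD (a known DIC
    pathology under poor mixing or strong non-normality) triggers a warning,
    not a failure.
    """
    if len(draws) < min_draws:
        raise ValueError(f"need >= {min_draws} retained draws, have {len(draws)}")
    if design is None:
        design = encode_design(
            ds,
            individual_covariates=spec.individual_covariates if spec.uses_x else (),
            area_covariates=spec.area_covariates if spec.uses_w else (),
            area_schema=area_schema,
        )
    y = ds.individuals["outcome"].to_numpy(dtype=float)
    dbar = float(draws.deviance.mean())
    lam_hat = linear_predictor(draws.mean_state(), design, spec)
    d_hat = -2.0 * log_likelihood(y, lam_hat)
    pd_ = dbar - d_hat
    if pd_ < 0:
        logger.warning("negative pD (%.3f): DIC may be unreliable here", pd_)
    return dbar + pd_, dbar, pd_


def spatial_fraction(sigma_u2: float, sigma_v2: float) -> float:
    """SF = sigma_u^2 / (sigma_u^2 + sigma_v^2), in [0, 1]."""
    if sigma_u2 < 0 or sigma_v2 < 0:
        raise ValueError("variances must be nonnegative")
    total = sigma_u2 + sigma_v2
    if total == 0:
        raise ValueError("SF undefined when both variances are zero")
    return sigma_u2 / total


def compare(
    ds: MultilevelDataset,
    graph: AreaGraph,
    specs: list[ModelSpec],
    mcmc: McmcSettings | None = None,
    seed: int | None = None,
    area_schema=None,
    keep_draws: bool = False,
) -> FitComparison:
    """Fit each variant on the same data with the same seed policy and
    tabulate Dbar, pD, DIC (and SF where the CAR component exists).

    SF is the posterior mean of the per-draw ratio of Eq-style raw variance
    parameters; it is reported only for variants that include u.
    """
    if seed is None:
        raise ValueError("seed is required")
    rows = {}
    kept: dict[str, PosteriorDraws] = {}
    for spec in specs:
        draws = fit(ds, graph, spec, mcmc=mcmc, seed=seed, area_schema=area_schema)
        dic_val, dbar, pd_ = dic(draws, ds, spec, area_schema=area_schema, min_draws=1)
        sf = np.nan
        if spec.uses_u:
            sf = float(
                np.mean(draws.sigma_u2 / (draws.sigma_u2 + draws.sigma_v2))
            )
        rows[spec.variant] = {"Dbar": dbar, "pD": pd_, "DIC": dic_val, "SF": sf}
        if keep_draws:
            kept[spec.variant] = draws
    table = pd.DataFrame(rows).T
    table.index.name = "variant"
    return FitComparison(table=table, draws=kept)
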