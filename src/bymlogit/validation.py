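"""End-to-end simulation studies used for package validation.

These run the full pipeline — generate a cohort with known truth, fit the
model variants by MCMC, summarize — and report coverage of credible
intervals, DIC orderings and spatial-fraction recovery.  They are called
by the test suite and the reproduction script; sizes are chosen to finish
on a single CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import McmcSettings, fit
from .model_core import ModelSpec
from .model_selection import dic
from .synthetic_data import SimulationConfig, simulate_cohort

__all__ = ["RecoveryStudy", "recovery_study", "sf_recovery"]

#: ground truth of the standard recovery scenario
RECOVERY_TRUTH = {
    "alpha": -1.1,
    "x1[b]": 0.4,
    "x2[b]": -0.4,
    "w1[T3]": 0.3,
    "sigma_u2": 0.5,
    "sigma_v2": 0.1,
}

RECOVERY_MCMC = McmcSettings(chains=1, iterations=10_000, burn_in=4_000, thin=6)


@dataclass
class RecoveryStudy:
    """Replicate-level results of the M4 parameter-recovery study."""

    n_replicates: int
    covered: dict[str, list[bool]] = field(default_factory=dict)
    dic_m4: list[float] = field(default_factory=list)
    dic_m1: list[float] = field(default_factory=list)
    sf_posterior_means: list[float] = field(default_factory=list)

    def coverage_counts(self) -> dict[str, int]:
        return {k: int(sum(v)) for k, v in self.covered.items()}

    @property
    def dic_m4_wins(self) -> int:
        return int(sum(d4 < d1 for d4, d1 in zip(self.dic_m4, self.dic_m1)))


def _recovery_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_areas=100,
        mean_individuals=80,
        alpha=RECOVERY_TRUTH["alpha"],
        covariate_probs={"x1": {"a": 0.5, "b": 0.5}, "x2": {"a": 0.5, "b": 0.5}},
        area_covariate_probs={"w1": {"T1": 0.34, "T2": 0.33, "T3": 0.33}},
        beta={"x1[b]": RECOVERY_TRUTH["x1[b]"], "x2[b]": RECOVERY_TRUTH["x2[b]"]},
        gamma={"w1[T3]": RECOVERY_TRUTH["w1[T3]"]},
        sigma_u2=RECOVERY_TRUTH["sigma_u2"],
        sigma_v2=RECOVERY_TRUTH["sigma_v2"],
        seed=seed,
    )


def recovery_study(
    n_replicates: int = 20,
    seed: int = 1,
    mcmc: McmcSettings = RECOVERY_MCMC,
) -> RecoveryStudy:
    """Simulate-and-refit study under the standard scenario.

    Per replicate: draw a 100-area x ~80-per-area cohort from the M4 truth,
    fit M4 and record whether each parameter's equal-tailed 95% CrI covers
    the truth, then fit the intercept-only M1 on the same data and record
    both DIC values.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
    study = RecoveryStudy(n_replicates=n_replicates)
    spec4 = ModelSpec(
        variant="M4", individual_covariates=("x1", "x2"), area_covariates=("w1",)
    )
    spec1 = ModelSpec(variant="M1")
    for rs in rep_seeds:
        ds, graph, _ = simulate_cohort(_recovery_config(rs))
        draws = fit(ds, graph, spec4, mcmc, seed=rs + 1)
        arrays = {
            "alpha": draws.alpha,
            "x1[b]": draws.beta[:, 0],
            "x2[b]": draws.beta[:, 1],
            "w1[T3]": draws.gamma[:, 1],
            "sigma_u2": draws.sigma_u2,
            "sigma_v2": draws.sigma_v2,
        }
        for name, arr in arrays.items():
            lo, hi = np.percentile(arr, [2.5, 97.5])
            study.covered.setdefault(name, []).append(
                bool(lo <= RECOVERY_TRUTH[name] <= hi)
            )
        study.sf_posterior_means.append(
            float(np.mean(draws.sigma_u2 / (draws.sigma_u2 + draws.sigma_v2)))
        )
        study.dic_m4.append(dic(draws, ds, spec4, min_draws=1)[0])
        d1 = fit(ds, graph, spec1, mcmc, seed=rs + 1)
        study.dic_m1.append(dic(d1, ds, spec1, min_draws=1)[0])
    return study


def sf_recovery(
    seed: int = 1,
    total_variance: float = 0.5,
    mcmc: McmcSettings | None = None,
) -> tuple[float, float]:
    """Posterior-mean SF under a 9:1 and a 1:9 split of the same total
    area-level variance; the first should exceed the second."""
    mcmc = mcmc or McmcSettings(chains=1, iterations=4_000, burn_in=2_000, thin=2)
    out = []
    spec = ModelSpec(variant="M4")
    for frac, sub in ((0.9, 1), (0.1, 2)):
        cfg = SimulationConfig(
            n_areas=64,
            mean_individuals=50,
            alpha=-1.1,
            sigma_u2=frac * total_variance,
            sigma_v2=(1 - frac) * total_variance,
            seed=seed + sub,
        )
        ds, graph, _ = simulate_cohort(cfg)
        draws = fit(ds, graph, spec, mcmc, seed=seed + 10 * sub)
        out.append(float(np.mean(draws.sigma_u2 / (draws.sigma_u2 + draws.sigma_v2))))
    return out[0], out[1]
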