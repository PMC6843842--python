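"""Descriptive table and univariate screening on a simulated cohort.

Mirrors the pre-modelling stage of a neighborhood-obesity analysis: counts
and column percents by outcome group, then per-stratum univariate logistic
screening whose selected covariates would feed the multilevel model.
"""

from bymlogit import SimulationConfig, describe, screen, simulate_cohort

cfg = SimulationConfig(
    n_areas=49,
    mean_individuals=120,
    alpha=-1.1,
    covariate_probs={
        "gender": {"male": 0.46, "female": 0.54},
        "age_group": {"19-39": 0.35, "40-59": 0.43, "60+": 0.22},
        "smoking": {"never": 0.62, "former": 0.16, "current": 0.22},
        "mvpa": {"no": 0.35, "yes": 0.65},
    },
    beta={"smoking[former]": 0.3, "mvpa[yes]": -0.12},
    sigma_u2=0.2,
    sigma_v2=0.05,
    seed=11,
)
ds, graph, _ = simulate_cohort(cfg)

table = describe(ds, covariates=["smoking", "mvpa"])
print(f"nonobese: {table.n_nonobese}, obese: {table.n_obese} "
      f"({100 * table.n_obese / ds.n_records:.1f}% of participants)")
print(table.formatted().to_string(index=False))
print()

result = screen(ds, covariates=["smoking", "mvpa"], threshold=0.05)
print("univariate Wald screening per gender x age stratum "
      "(selected -> enters the multilevel model for that stratum):")
print(result.to_string(index=False))
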