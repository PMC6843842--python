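"""Pre-modelling stage: descriptive tables and univariate logistic screening.

Analyses are run separately within the six gender x age strata.  For each
stratum, every candidate covariate is screened with a univariate maximum-
likelihood logistic regression (Newton-type fit via statsmodels); a
covariate is selected for the multilevel model when its Wald test across
all non-reference levels falls below the significance threshold (default
0.05 — the choice of threshold is a configurable analysis assumption).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import MultilevelDataset

logger = logging.getLogger(__name__)

STRATA = [(g, a) for g in ("male", "female") for a in ("19-39", "40-59", "60+")]

__all__ = [
    "DescriptiveTable",
    "UnivariateFit",
    "describe",
    "fit_univariate_logistic",
    "screen",
    "STRATA",
]


@dataclass
class DescriptiveTable:
    """Counts and column percents per covariate level, by outcome group."""

    table: pd.DataFrame  # columns: covariate, level, n_nonobese, pct_nonobese, n_obese, pct_obese
    n_nonobese: int
    n_obese: int

    def formatted(self) -> pd.DataFrame:
        """'n (%)' cells with one decimal, mirroring the usual table layout."""
        out = self.table.copy()
        out["nonobese"] = [
            f"{int(n)} ({p:.1f})" for n, p in zip(out.n_nonobese, out.pct_nonobese)
        ]
        out["obese"] = [
            f"{int(n)} ({p:.1f})" for n, p in zip(out.n_obese, out.pct_obese)
        ]
        return out[["covariate", "level", "nonobese", "obese"]]


@dataclass
class UnivariateFit:
    covariate: str
    levels: list[str]  # non-reference levels retained in the fit
    log_or: np.ndarray
    se: np.ndarray
    wald_p: float  # joint Wald p-value across retained levels
    separated_levels: list[str]

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.log_or)


def describe(ds: MultilevelDataset, covariates: list[str] | None = None) -> DescriptiveTable:
    """Counts and column percents within the nonobese and obese groups."""
    df = ds.individuals
    if df.empty:
        raise ValueError("dataset is empty")
    covs = covariates or ds.schema.names
    y = df["outcome"].astype(int)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    rows = []
    for cov in covs:
        for level in ds.schema.levels.get(cov, sorted(df[cov].unique())):
            in_level = df[cov] == level
            c0 = int((in_level & (y == 0)).sum())
            c1 = int((in_level & (y == 1)).sum())
            rows.append(
                {
                    "covariate": cov,
                    "level": level,
                    "n_nonobese": c0,
                    "pct_nonobese": 100.0 * c0 / n0 if n0 else np.nan,
                    "n_obese": c1,
                    "pct_obese": 100.0 * c1 / n1 if n1 else np.nan,
                }
            )
    return DescriptiveTable(table=pd.DataFrame(rows), n_nonobese=n0, n_obese=n1)


def fit_univariate_logistic(
    y: np.ndarray | pd.Series,
    x: pd.Series | np.ndarray,
    reference: str | None = None,
) -> UnivariateFit:
    """Maximum-likelihood logistic fit of a binary outcome on one
    categorical covariate (dummy coded against ``reference``).

    Levels exhibiting complete separation (all-0 or all-1 outcomes) are
    flagged and excluded from the Wald test rather than crashing the fit.
    """
    y = np.asarray(y, dtype=float)
    x = pd.Series(np.asarray(x, dtype=object), name=getattr(x, "name", "x"))
    if len(set(y)) < 2:
        raise ValueError("both outcome classes must be present")
    levels = sorted(map(str, x.unique()))
    if len(levels) < 2:
        raise ValueError(f"covariate {x.name!r} has a single observed level")
    ref = str(reference) if reference is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference {ref!r} not observed")

    separated = []
    usable = []
    for lv in levels:
        mask = x.astype(str) == lv
        ybar = y[mask].mean()
        if lv != ref and (ybar == 0.0 or ybar == 1.0):
            separated.append(lv)
        elif lv != ref:
            usable.append(lv)
    if separated:
        logger.warning(
            "complete separation in levels %s of %r; excluded from Wald test",
            separated,
            x.name,
        )
    keep = x.astype(str).isin([ref] + usable).to_numpy()
    xk = x.astype(str)[keep]
    yk = y[keep]
    design = np.column_stack(
        [np.ones(keep.sum())] + [(xk == lv).to_numpy(dtype=float) for lv in usable]
    )
    res = sm.Logit(yk, design).fit(disp=0)
    log_or = np.asarray(res.params[1:])
    se = np.asarray(res.bse[1:])
    if usable:
        contrast = np.hstack([np.zeros((len(usable), 1)), np.eye(len(usable))])
        wald_p = float(res.wald_test(contrast, scalar=True).pvalue)
    else:
        wald_p = np.nan
    return UnivariateFit(
        covariate=str(x.name),
        levels=usable,
        log_or=log_or,
        se=se,
        wald_p=wald_p,
        separated_levels=separated,
    )


def screen(
    ds: MultilevelDataset,
    covariates: list[str] | None = None,
    threshold: float = 0.05,
    stratify: bool = True,
) -> pd.DataFrame:
    """Univariate screening per gender x age stratum.

    Returns a long table (gender, age_group, covariate, wald_p, selected);
    ``selected`` covariates feed the multilevel model's covariate list for
    that stratum.  Empty strata are skipped with a warning.
    """
    df = ds.individuals
    covs = covariates or ds.schema.names
    strata = STRATA if stratify else [(None, None)]
    rows = []
    for g, a in strata:
        if g is None:
            sub = df
        else:
            if "gender" not in df.columns or "age_group" not in df.columns:
                raise ValueError("stratified screening needs gender and age_group columns")
            sub = df[(df["gender"] == g) & (df["age_group"] == a)]
        if sub.empty:
            logger.warning("stratum (%s, %s) is empty; skipped", g, a)
            continue
        for cov in covs:
            try:
                res = fit_univariate_logistic(
                    sub["outcome"].to_numpy(), sub[cov], reference=ds.schema.ref(cov)
                )
                p = res.wald_p
            except ValueError:
                p = np.nan
            rows.append(
                {
                    "gender": g,
                    "age_group": a,
                    "covariate": cov,
                    "wald_p": p,
                    "selected": bool(p <= threshold) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)
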