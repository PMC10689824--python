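"""Incubation outcomes: cumulative respiration and treatment effect sizes.

A 10-day incubation crosses two soils (basalt, sandstone) with three
treatments (control, +glucose-C, +PO4-P), five replicates per cell.
Respiration rates are measured on days 0 (pre-treatment), 1, 2, 3, 4, 8 and
10 and integrated by the trapezoid rule; day-10 C pools (MBC, PLFA fractions,
NLFA, PHB) are compared to the control arm as log response ratios
rr = ln(mean_treatment / mean_control) with delta-method standard errors and
normal 95% intervals.  An effect is called significant when its interval
excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DegenerateDesignError, ValidationError

SOILS = ("basalt", "sandstone")
TREATMENTS = ("control", "glucose_c", "po4_p")
MEASUREMENT_DAYS = (0, 1, 2, 3, 4, 8, 10)
POOL_VARIABLES = (
    "mbc",
    "plfa_total_c",
    "plfa_fungal_c",
    "plfa_bacterial_c",
    "nlfa_c",
    "phb_c",
)

Z_95 = 1.959963984540054


@dataclass
class IncubationSample:
    """One jar: respiration time series plus day-10 C pools (ug C g soil-1)."""

    soil: str
    treatment: str
    replicate: int
    respiration_series: list[tuple[float, float]]  # (day, rate ug CO2-C g-1 d-1)
    day10_pools: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.soil not in SOILS:
            raise ValidationError(f"unknown soil {self.soil!r}")
        if self.treatment not in TREATMENTS:
            raise ValidationError(f"unknown treatment {self.treatment!r}")
        days = [d for d, _ in self.respiration_series]
        if days and (days[0] != 0 or any(b <= a for a, b in zip(days, days[1:]))):
            raise ValidationError("days must be strictly increasing from 0")
        for k, v in self.day10_pools.items():
            if v < 0:
                raise ValidationError(f"pool {k} is negative")


@dataclass
class EffectSize:
    """Log response ratio for one treatment x variable x soil combination."""

    variable: str
    soil: str
    treatment: str
    rr: float
    se: float
    ci_low: float
    ci_high: float
    n_treatment: int
    n_control: int

    @property
    def significant(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


def cumulative_respiration(series: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal integral of the rate series over its measured days."""
    if len(series) < 2:
        raise ValidationError("need >= 2 time points")
    days = np.array([d for d, _ in series], dtype=float)
    rates = np.array([r for _, r in series], dtype=float)
    if (np.diff(days) <= 0).any():
        raise ValidationError("days must be strictly increasing")
    return float(np.trapezoid(rates, days))


def response_ratio(
    treatment_values, control_values, variable: str = "", soil: str = "", treatment: str = ""
) -> EffectSize:
    """rr = ln(mean_t / mean_c) with delta-method SE and 95% normal CI."""
    t = np.asarray(treatment_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if len(t) < 2 or len(c) < 2:
        raise ValidationError("need >= 2 values per arm")
    if (t <= 0).any() or (c <= 0).any():
        raise ValidationError("response-ratio values must be strictly positive")
    mt, mc = t.mean(), c.mean()
    rr = float(np.log(mt / mc))
    se = float(
        np.sqrt(t.var(ddof=1) / (len(t) * mt**2) + c.var(ddof=1) / (len(c) * mc**2))
    )
    return EffectSize(
        variable=variable,
        soil=soil,
        treatment=treatment,
        rr=rr,
        se=se,
        ci_low=rr - Z_95 * se,
        ci_high=rr + Z_95 * se,
        n_treatment=len(t),
        n_control=len(c),
    )


def effect_table(samples: Sequence[IncubationSample]) -> pd.DataFrame:
    """All treatment-vs-control log response ratios, per soil and variable.

    Variables are cumulative respiration plus every day-10 pool present.
    """
    rows = []
    df = samples_to_frame(samples)
    for soil in sorted(df["soil"].unique()):
        sub = df[df["soil"] == soil]
        ctrl = sub[sub["treatment"] == "control"]
        if ctrl.empty:
            raise DegenerateDesignError(f"soil {soil!r} has no control arm")
        for trt in [t for t in TREATMENTS if t != "control"]:
            arm = sub[sub["treatment"] == trt]
            if arm.empty:
                continue
            for var in ["cumulative_respiration", *POOL_VARIABLES]:
                if var not in sub.columns or arm[var].isna().all():
                    continue
                es = response_ratio(
                    arm[var].to_numpy(), ctrl[var].to_numpy(),
                    variable=var, soil=soil, treatment=trt,
                )
                rows.append(
                    {
                        "soil": soil,
                        "treatment": trt,
                        "variable": var,
                        "rr": es.rr,
                        "se": es.se,
                        "ci_low": es.ci_low,
                        "ci_high": es.ci_high,
                        "significant": es.significant,
                        "n_treatment": es.n_treatment,
                        "n_control": es.n_control,
                    }
                )
    return pd.DataFrame(rows)


def samples_to_frame(samples: Sequence[IncubationSample]) -> pd.DataFrame:
    """Wide per-jar table with cumulative respiration and day-10 pools."""
    rows = []
    for s in samples:
        row = {
            "soil": s.soil,
            "treatment": s.treatment,
            "replicate": s.replicate,
            "cumulative_respiration": cumulative_respiration(s.respiration_series),
        }
        row.update(s.day10_pools)
        rows.append(row)
    return pd.DataFrame(rows)


def treatment_contrast_with_covariate(
    samples: Sequence[IncubationSample] | pd.DataFrame,
    response: str,
    covariate: str,
) -> pd.DataFrame:
    """Factorial ANOVA of log(response) with a log covariate.

    OLS of log(response) ~ log(covariate) + soil * treatment; returns the
    type-II ANOVA table (F and p per term) with the covariate coefficient
    attached as metadata columns.
    """
    df = samples if isinstance(samples, pd.DataFrame) else samples_to_frame(samples)
    if df["soil"].nunique() < 2 or df["treatment"].nunique() < 2:
        raise DegenerateDesignError("need both soils and >= 2 treatments")
    if (df[response] <= 0).any() or (df[covariate] <= 0).any():
        raise ValidationError("response and covariate must be positive for log ANOVA")
    work = df.assign(
        _ly=np.log(df[response].astype(float)),
        _lx=np.log(df[covariate].astype(float)),
    )
    model = smf.ols("_ly ~ _lx + C(soil) * C(treatment)", data=work).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise DegenerateDesignError("rank-deficient incubation design")
    table = sm.stats.anova_lm(model, typ=2).rename(
        index={"_lx": f"log_{covariate}"}
    )
    table = table.reset_index().rename(columns={"index": "term"})
    table["covariate_coef"] = model.params["_lx"]
    table["covariate_se"] = model.bse["_lx"]
    return table
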