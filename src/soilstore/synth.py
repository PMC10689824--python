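"""Synthetic gradient and incubation datasets with the assumed structure.

The gradient generator emulates the field design (4 soil types x 2 sites x
3 replicates = 24 samples): log-linear storage-biomass scaling with
soil-type allocation intercepts, Gaussian random site intercepts, lognormal
replicate noise, fungal fractions that rise from fertile to infertile
classes, and a phosphodiesterase activity that (optionally) drives PHB
allocation.  The incubation generator emulates the 2 soils x 3 treatments x
5 replicates design with multiplicative treatment effects on day-10 pools
and on post-treatment respiration rates.

All noise is lognormal on the measured scale (normal on the log scale), so
concentrations are positive by construction, and every draw is reproducible
from the config's single root seed via per-component spawned streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from . import allocation as alc
from . import incubation as inc
from .data import FERTILE_TYPES, GradientDataset, PlfaProfile, SOIL_TYPES, _validate_rows
from .errors import ValidationError

LN = math.log

#: soil-type geometric means calibrated once against the site-mean fixture
_PLFA_LOG_MEAN = {
    "basalt": LN(54.0),
    "shale": LN(44.0),
    "ironstone": LN(18.0),
    "sandstone": LN(19.5),
}

_CHEMISTRY_MEANS = {
    #                soc      sol_c  tot_n  tot_p  mehlich  mbc   mbp   pme   gluc
    "basalt": (0.037, 77.0, 2400.0, 430.0, 1.30, 413.0, 33.0, 611.0, 133.0),
    "shale": (0.035, 78.0, 2265.0, 166.0, 1.90, 373.0, 30.0, 768.0, 320.0),
    "ironstone": (0.013, 57.0, 905.0, 125.0, 0.10, 195.0, 2.1, 644.0, 96.0),
    "sandstone": (0.013, 60.0, 875.0, 65.0, 0.12, 196.0, 8.0, 780.0, 107.0),
}
_CHEM_FIELDS = (
    "total_organic_c",
    "soluble_organic_c",
    "total_n",
    "total_p",
    "mehlich_po4",
    "mbc",
    "mbp",
    "phosphomonoesterase",
    "glucosidase",
)


def _default_intercepts() -> dict[str, dict[str, float]]:
    """Log-scale storage at the mean covariate; infertile = 2.5 x fertile
    for NLFA and PHB, no contrast for trehalose (as observed)."""
    out: dict[str, dict[str, float]] = {"nlfa_c": {}, "phb_c": {}, "trehalose_c": {}}
    for t in SOIL_TYPES:
        fertile = t in FERTILE_TYPES
        out["nlfa_c"][t] = LN(12.0) if fertile else LN(12.0 * 2.5)
        out["phb_c"][t] = LN(16.0) if fertile else LN(16.0 * 2.5)
        out["trehalose_c"][t] = LN(5.0)
    return out


def _default_incubation_effects() -> dict[tuple[str, str], dict[str, float]]:
    """Multiplicative treatment effects mirroring the incubation findings:
    glucose boosts respiration, MBC, fungal PLFA, NLFA and PHB in both
    soils; phosphate boosts respiration (~2x) and bacterial PLFA only in
    the sandstone soil."""
    glucose = {
        "respiration": 4.0,
        "mbc": 4.0,
        "plfa_total_c": 2.0,
        "plfa_fungal_c": 3.0,
        "plfa_bacterial_c": 1.0,
        "nlfa_c": 3.0,
        "phb_c": 2.5,
    }
    nul = {k: 1.0 for k in glucose}
    po4_sandstone = dict(nul, respiration=2.0, plfa_bacterial_c=1.8, plfa_total_c=1.3)
    return {
        ("basalt", "glucose_c"): dict(glucose),
        ("sandstone", "glucose_c"): dict(glucose),
        ("basalt", "po4_p"): dict(nul),
        ("sandstone", "po4_p"): po4_sandstone,
    }


@dataclass
class SyntheticConfig:
    """Generative parameters for gradient and incubation datasets."""

    seed: int = 0
    soil_types: tuple[str, ...] = SOIL_TYPES
    sites_per_type: int = 2
    reps_per_site: int = 3
    plfa_log_mean: dict[str, float] = field(default_factory=lambda: dict(_PLFA_LOG_MEAN))
    plfa_log_sd: float = 0.25  # replicate CV implied by printed site SEs (SE*sqrt(3))
    allocation_intercepts: dict[str, dict[str, float]] = field(default_factory=_default_intercepts)
    covariate_slope: float = 1.0
    site_sd: float = 0.1
    residual_sd: float = 0.2
    fungal_fraction: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"fertile": (0.19, 0.02), "infertile": (0.37, 0.03)}
    )
    phosphatase_link: float = 0.8
    pde_log_mean: float = LN(280.0)
    pde_log_sd: float = 0.4
    chem_log_sd: float = 0.15
    incubation_n: int = 5
    resp_targets: dict[str, float] = field(
        default_factory=lambda: {"basalt": 454.0, "sandstone": 201.0}
    )
    incubation_baselines: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "basalt": {
                "mbc": 553.0, "plfa_total_c": 450.0, "plfa_fungal_c": 65.0,
                "plfa_bacterial_c": 290.0, "nlfa_c": 22.0, "phb_c": 33.0,
            },
            "sandstone": {
                "mbc": 235.0, "plfa_total_c": 165.0, "plfa_fungal_c": 41.0,
                "plfa_bacterial_c": 65.0, "nlfa_c": 20.0, "phb_c": 41.0,
            },
        }
    )
    incubation_effects: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=_default_incubation_effects
    )
    incubation_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        for name in ("plfa_log_sd", "site_sd", "residual_sd", "pde_log_sd",
                     "chem_log_sd", "incubation_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.sites_per_type < 1 or self.reps_per_site < 1 or self.incubation_n < 1:
            raise ValidationError("design counts must be >= 1")
        for cls, (mu, sd) in self.fungal_fraction.items():
            if not (0 < mu < 1) or sd < 0:
                raise ValidationError(f"fungal_fraction[{cls}] invalid")


def null_gradient_config(seed: int = 0) -> SyntheticConfig:
    """Config with no soil-type allocation contrast and no phosphatase link."""
    cfg = SyntheticConfig(seed=seed, phosphatase_link=0.0)
    for compound, per_type in cfg.allocation_intercepts.items():
        base = per_type[cfg.soil_types[0]]
        for t in cfg.soil_types:
            per_type[t] = base
    return cfg


def null_incubation_config(seed: int = 0) -> SyntheticConfig:
    """Config with every treatment multiplier set to 1 (no true effects)."""
    cfg = SyntheticConfig(seed=seed)
    for key, effects in cfg.incubation_effects.items():
        cfg.incubation_effects[key] = {k: 1.0 for k in effects}
    return cfg


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_gradient(config: SyntheticConfig) -> GradientDataset:
    """Replicate-level gradient dataset (default 24 samples, 8 sites)."""
    rng_site, rng_plfa, rng_chem, rng_storage, rng_pde = _streams(config.seed, 5)

    rows = []
    site_effects: dict[str, float] = {}
    for t in config.soil_types:
        for s in range(1, config.sites_per_type + 1):
            site_effects[f"{t}_site_{s}"] = rng_site.normal(0.0, config.site_sd)

    for t in config.soil_types:
        fertile = t in FERTILE_TYPES
        cls = "fertile" if fertile else "infertile"
        ff_mu, ff_sd = config.fungal_fraction[cls]
        chem_mu = dict(zip(_CHEM_FIELDS, _CHEMISTRY_MEANS[t]))
        for s in range(1, config.sites_per_type + 1):
            site_id = f"{t}_site_{s}"
            for r in range(1, config.reps_per_site + 1):
                lplfa = rng_plfa.normal(config.plfa_log_mean[t], config.plfa_log_sd)
                ff = float(np.clip(rng_plfa.normal(ff_mu, ff_sd), 0.02, 0.9))
                plfa_total = math.exp(lplfa)
                plfa_bacterial = (1.0 - ff) * 0.9 * plfa_total
                plfa_fungal = ff * 0.9 * plfa_total
                gp_frac = float(np.clip(rng_plfa.normal(0.5, 0.05), 0.2, 0.8))
                row = {
                    "sample_id": f"{site_id}_rep_{r}",
                    "site_id": site_id,
                    "soil_type": t,
                    "fertility_class": cls,
                    "plfa_total": plfa_total,
                    "plfa_bacterial": plfa_bacterial,
                    "plfa_fungal": plfa_fungal,
                    "plfa_gram_pos": gp_frac * plfa_bacterial,
                    "plfa_gram_neg": (1.0 - gp_frac) * plfa_bacterial,
                    "_site_effect": site_effects[site_id],
                }
                for name in _CHEM_FIELDS:
                    row[name] = chem_mu[name] * math.exp(
                        rng_chem.normal(0.0, config.chem_log_sd)
                    )
                row["total_organic_c"] = float(np.clip(row["total_organic_c"], 1e-4, 0.6))
                rows.append(row)

    df = pd.DataFrame(rows)
    mean_ltot = float(np.mean(np.log(df["plfa_total"])))
    mean_lbact = float(np.mean(np.log(df["plfa_bacterial"])))
    lpde = rng_pde.normal(config.pde_log_mean, config.pde_log_sd, len(df))
    df["phosphodiesterase"] = np.exp(lpde)

    for compound in ("nlfa_c", "phb_c", "trehalose_c"):
        cov_log = (
            np.log(df["plfa_bacterial"]) - mean_lbact
            if compound == "phb_c"
            else np.log(df["plfa_total"]) - mean_ltot
        )
        mu = (
            df["soil_type"].map(config.allocation_intercepts[compound]).to_numpy()
            + config.covariate_slope * cov_log.to_numpy()
            + df["_site_effect"].to_numpy()
        )
        if compound == "phb_c":
            mu = mu + config.phosphatase_link * (lpde - config.pde_log_mean)
        noise = rng_storage.normal(0.0, config.residual_sd, len(df))
        df[compound] = np.exp(mu + noise)

    df = df.drop(columns=["_site_effect"])
    _validate_rows(df.reset_index(drop=True))
    return GradientDataset(frame=df.reset_index(drop=True), level="replicate")


#: relative shape of the control respiration rate curve at the measured days
_RESP_DAYS = np.array(inc.MEASUREMENT_DAYS, dtype=float)
_RESP_SHAPE = np.array([1.2, 1.15, 1.05, 1.0, 0.95, 0.85, 0.8])


def generate_incubation(config: SyntheticConfig) -> list[inc.IncubationSample]:
    """2 soils x {control, +glucose-C, +PO4-P} x incubation_n jars.

    Control rate curves are scaled so their cumulative integral equals the
    configured soil target; treatment multipliers act on post-treatment days
    only (the day-0 rate is measured before amendment).  Replicate noise is
    mean-one lognormal.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    sd = config.incubation_noise_sd
    shift = -0.5 * sd**2  # mean-one lognormal
    base_integral = float(np.trapezoid(_RESP_SHAPE, _RESP_DAYS))
    samples = []
    for soil in ("basalt", "sandstone"):
        base_rates = _RESP_SHAPE * (config.resp_targets[soil] / base_integral)
        for trt in inc.TREATMENTS:
            effects = config.incubation_effects.get((soil, trt), {})
            for rep in range(1, config.incubation_n + 1):
                jar = math.exp(rng.normal(shift, sd)) if sd > 0 else 1.0
                rates = base_rates * jar
                mult = effects.get("respiration", 1.0)
                rates = np.where(_RESP_DAYS > 0, rates * mult, rates)
                pools = {}
                for var, base in config.incubation_baselines[soil].items():
                    noise = math.exp(rng.normal(shift, sd)) if sd > 0 else 1.0
                    pools[var] = base * effects.get(var, 1.0) * noise
                samples.append(
                    inc.IncubationSample(
                        soil=soil,
                        treatment=trt,
                        replicate=rep,
                        respiration_series=list(zip(_RESP_DAYS.tolist(), rates.tolist())),
                        day10_pools=pools,
                    )
                )
    return samples


def generate_null_profiles(
    seed: int, n_per_group: int = 6, n_markers: int = 12
) -> tuple[list[PlfaProfile], list[str]]:
    """Structure-free PLFA profiles labelled by soil type (for type-I error)."""
    rng = np.random.default_rng(seed)
    marker_mu = rng.uniform(0.0, 2.0, n_markers)
    profiles, labels = [], []
    k = 0
    for t in SOIL_TYPES:
        for _ in range(n_per_group):
            amounts = np.exp(rng.normal(marker_mu, 0.3))
            profiles.append(
                PlfaProfile(
                    sample_id=f"s{k}",
                    marker_amounts={f"m{j:02d}": float(a) for j, a in enumerate(amounts)},
                )
            )
            labels.append(t)
            k += 1
    return profiles, labels


def recovery_experiment(
    n_replicates: int,
    config: SyntheticConfig,
    analysis: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Repeat generate -> analyse with incremented seeds; summarise.

    Stages
    ------
    allocation
        LRT rejection rate for the soil-type term on NLFA allocation, plus
        the infertile:fertile EMM fold difference (mean, and the fraction of
        replicates landing in [2, 3]).
    slope
        Continuous-predictor fit of PHB allocation on log phosphodiesterase:
        rejection rate, mean slope bias, and CI coverage of the true slope.
    permanova
        Type-I error of PERMANOVA on structure-free composition data.
    response_ratio
        CI coverage of zero across all effect-table cells under the config's
        (possibly null) incubation effects.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    known = {"allocation", "slope", "permanova", "response_ratio"}
    if analysis not in known:
        raise ValueError(f"unknown analysis stage {analysis!r}; one of {sorted(known)}")

    fertile = [t for t in config.soil_types if t in FERTILE_TYPES]
    infertile = [t for t in config.soil_types if t not in FERTILE_TYPES]
    rows = []

    if analysis == "allocation":
        true_fold = math.exp(
            np.mean([config.allocation_intercepts["nlfa_c"][t] for t in infertile])
            - np.mean([config.allocation_intercepts["nlfa_c"][t] for t in fertile])
        )
        rejected, folds = [], []
        for i in range(n_replicates):
            data = generate_gradient(replace(config, seed=config.seed + 1 + i))
            fit = alc.fit_allocation_model(data, "nlfa_c", "plfa_total", "soil_type")
            rejected.append(fit.p_value < alpha)
            folds.append(fit.emm_fold_difference(infertile, fertile))
        folds_arr = np.array(folds)
        rows += [
            ("allocation", "rejection_rate", float(np.mean(rejected))),
            ("allocation", "mean_fold", float(folds_arr.mean())),
            ("allocation", "fold_in_2_3", float(np.mean((folds_arr >= 2) & (folds_arr <= 3)))),
            ("allocation", "bias_log_fold", float(np.mean(np.log(folds_arr)) - math.log(true_fold))),
        ]
    elif analysis == "slope":
        true_slope = config.phosphatase_link
        rejected, slopes, covered = [], [], []
        for i in range(n_replicates):
            data = generate_gradient(replace(config, seed=config.seed + 1 + i))
            pred = np.log(data.frame["phosphodiesterase"].to_numpy())
            fit = alc.test_continuous_predictor(
                data, "phb_c", "plfa_bacterial", pred
            )
            est, lo, hi = fit.emm["slope"]
            rejected.append(fit.p_value < alpha)
            slopes.append(est)
            covered.append(lo <= true_slope <= hi)
        rows += [
            ("slope", "rejection_rate", float(np.mean(rejected))),
            ("slope", "bias", float(np.mean(slopes) - true_slope)),
            ("slope", "coverage", float(np.mean(covered))),
        ]
    elif analysis == "permanova":
        rejected = []
        for i in range(n_replicates):
            profiles, labels = generate_null_profiles(config.seed + 1 + i)
            _, mat = alc.composition_matrix(profiles)
            d = alc.bray_curtis_matrix(mat)
            res = alc.permanova(d, labels, n_permutations=199, seed=config.seed + 1 + i)
            rejected.append(res.p_value < alpha)
        rows.append(("permanova", "type_i_error", float(np.mean(rejected))))
    else:  # response_ratio
        covered_all = []
        for i in range(n_replicates):
            samples = generate_incubation(replace(config, seed=config.seed + 1 + i))
            table = inc.effect_table(samples)
            for _, r in table.iterrows():
                key = (r["soil"], r["treatment"])
                var = "respiration" if r["variable"] == "cumulative_respiration" else r["variable"]
                true_mult = config.incubation_effects.get(key, {}).get(var, 1.0)
                if true_mult == 1.0:
                    covered_all.append(r["ci_low"] <= 0.0 <= r["ci_high"])
        rows.append(("response_ratio", "null_coverage", float(np.mean(covered_all))))

    return pd.DataFrame(rows, columns=["stage", "metric", "value"]).assign(
        n_replicates=n_replicates
    )
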