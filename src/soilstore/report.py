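"""End-to-end fixture pipeline: summary indices plus both model sweeps."""

from __future__ import annotations

from typing import Any

import numpy as np

from . import data, stoich


def fixture_summaries(dataset: data.GradientDataset | None = None) -> dict[str, Any]:
    """Range endpoints, per-SOC means and composition contrast from the
    packaged site-mean table."""
    ds = dataset if dataset is not None else data.load_table1_fixture()
    out: dict[str, Any] = {"n_records": len(ds)}
    for fld, stat in [
        ("nlfa_c", "max"),
        ("phb_c", "max"),
        ("trehalose_c", "min"),
        ("total_n", "max"),
        ("nlfa_c", "min"),
        ("phb_c", "min"),
    ]:
        value, sid = data.summarise_range(ds, fld, stat)
        out[f"{fld}_{stat}"] = {"value": value, "sample_id": sid}
    for fld in ("nlfa_per_soc", "phb_per_soc", "trehalose_per_soc"):
        value, _ = data.summarise_range(ds, fld, "mean")
        out[f"{fld}_mean"] = value
    out["mean_storage_fraction_of_mbc"] = data.mean_storage_fraction(ds)
    out["fungal_bacterial_fold_infertile_vs_fertile"] = data.fungal_bacterial_contrast(ds)
    out["fungal_bacterial_ratio"] = {
        s.sample_id: data.fungal_bacterial_ratio(s) for s in ds.samples()
    }
    return out


def model_predictions(
    cp_span: float = 30.0, n_points: int = 101
) -> dict[str, Any]:
    """Normalised flux sweeps for both soil parameterisations, all modes.

    The grid spans baseline/cp_span .. baseline*cp_span (log-spaced), wide
    enough that both soils cross their threshold element ratio.
    """
    out: dict[str, Any] = {}
    for soil, params in stoich.SOIL_PARAMS.items():
        sweep = stoich.sweep_gradient(
            "all", params,
            cp_min=params.baseline_cp / cp_span,
            cp_max=params.baseline_cp * cp_span,
            n_points=n_points,
        )
        out[soil] = {
            "ter": sweep.ter,
            "baseline_cp": sweep.baseline_cp,
            "baseline_limitation": stoich.classify_limitation(params.baseline_cp, params),
            "frame": stoich.sweep_to_frame(sweep),
        }
    return out


def acceptance_values(dataset: data.GradientDataset | None = None) -> dict[str, dict[str, float]]:
    """The six headline fixture quantities, keyed t1..t6.

    t1 NLFA max, t2 infertile:fertile fungal-bacterial fold difference,
    t3 PHB max, t4 trehalose min, t5 total N max (all ug g-1 soil scale),
    t6 mean per-SOC NLFA (ug C g SOC-1).
    """
    ds = dataset if dataset is not None else data.load_table1_fixture()
    summ = fixture_summaries(ds)
    n = len(ds)
    return {
        "t1": {"value": summ["nlfa_c_max"]["value"], "n": n},
        "t2": {"value": summ["fungal_bacterial_fold_infertile_vs_fertile"], "n": n},
        "t3": {"value": summ["phb_c_max"]["value"], "n": n},
        "t4": {"value": summ["trehalose_c_min"]["value"], "n": n},
        "t5": {"value": summ["total_n_max"]["value"], "n": n},
        "t6": {"value": summ["nlfa_per_soc_mean"], "n": n},
    }


def reproduce_report() -> dict[str, Any]:
    """Consolidated fixture + model report (JSON-serialisable)."""
    summaries = fixture_summaries()
    models = model_predictions()
    report: dict[str, Any] = {
        "fixture_summaries": {
            k: v for k, v in summaries.items() if k != "fungal_bacterial_ratio"
        },
        "acceptance_values": acceptance_values(),
        "model": {},
    }
    for soil, info in models.items():
        frame = info["frame"]
        report["model"][soil] = {
            "ter": info["ter"],
            "baseline_cp": info["baseline_cp"],
            "baseline_limitation": info["baseline_limitation"],
            "n_points": int(frame["cp_ratio"].nunique()),
            "max_balance_residual": float(
                np.abs(
                    frame["u_c"]
                    - (frame["growth"] + frame["respiration"] + frame["storage_net"])
                ).max()
            ),
        }
    return report
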