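"""End-to-end orchestration: CSV inputs -> fits -> summary tables and reports.

`run_kinetics` composes the lab-side chain (decay fitting -> collision-theory
gamma -> mechanism fit -> ambient extrapolation), `run_field` the field-side
ratio analysis, and `run_synthesize` writes synthetic fixture CSVs from a
scenario file. Every run drops a machine-readable provenance block (config
hash, seed, package version) next to its outputs so results can be traced to
the exact configuration that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .constants import (
    AMBIENT_NO2_PPBV,
    BENCHMARK_TIME_S,
    COARSE_CUTOFF_UM,
    MECHANISM_REF_PPBV,
    P_STD,
    T_STD,
)
from .collision_kinetics import (
    SubstrateRecord,
    lifetime_hours,
    reaction_probability,
    write_substrate_table,
)
from .core_units import PY_NO2, GasConditions
from .decay_kinetics import (
    degradation_percent,
    dnp_flag,
    product_yield,
    read_decay_csv,
    read_products_csv,
    select_decay_model,
    write_decay_csv,
)
from .field_ratios import (
    dust_effect_report,
    format_dust_report,
    read_field_csv,
    write_field_csv,
)
from .mechanism_fitting import (
    RateCurve,
    compare_mechanisms,
    fit_lh_no2,
    predict_k_obs,
    write_rate_curve_csv,
)
from .synthetic_data import (
    DecayScenario,
    FieldScenario,
    generate_decay_series,
    generate_field_dataset,
    generate_rate_curve,
)

__all__ = ["RunConfig", "run_kinetics", "run_field", "run_synthesize", "provenance"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration shared by the pipeline subcommands."""

    decay_csv: Optional[str] = None
    products_csv: Optional[str] = None
    field_csv: Optional[str] = None
    scenario_file: Optional[str] = None
    outdir: str = "nitrodust-out"
    temperature: float = T_STD
    pressure: float = P_STD
    speed_convention: str = "mean"
    coarse_cutoff_um: float = COARSE_CUTOFF_UM
    ambient_ppbv: float = AMBIENT_NO2_PPBV
    mechanism_ref_ppbv: float = MECHANISM_REF_PPBV
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**data)


def provenance(config: RunConfig) -> dict:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return {
        "config": dataclasses.asdict(config),
        "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
    }


def _write_provenance(config: RunConfig, outdir: Path) -> None:
    with open(outdir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance(config), fh, indent=2, default=str)
        fh.write("\n")


def run_kinetics(config: RunConfig) -> dict:
    """Decay CSVs -> per-substrate kinetic summary, mechanism fits, and
    ambient extrapolation.

    Each (substrate, NO2 level) series is fitted with F-test model selection;
    gamma is derived at that series' conditions. Substrates observed at >= 4
    NO2 levels get both mechanism fits plus a Langmuir-Hinshelwood
    extrapolation of k_obs, gamma and lifetime to the ambient mixing ratio.
    Writes substrate_table.csv, mechanism_report.json and provenance.json.
    """
    if config.decay_csv is None:
        raise ValueError("run_kinetics requires decay_csv")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series_list = read_decay_csv(
        config.decay_csv, temperature=config.temperature, pressure=config.pressure
    )
    products = read_products_csv(config.products_csv) if config.products_csv else {}

    records: list[SubstrateRecord] = []
    by_substrate: dict[str, list[tuple[float, float, float]]] = {}
    for series in series_list:
        if series.substrate in products:
            series.product_points = products[series.substrate]
        fit = select_decay_model(series)
        logger.info(
            "%s @ %.3g ppmv: %s model, k_obs = %.3g +/- %.3g s^-1 (rss %.3g)",
            series.substrate, series.conditions.ppmv, fit.model,
            fit.k_obs, fit.k_obs_se, fit.rss,
        )
        gamma = reaction_probability(
            fit.k_obs, PY_NO2, series.conditions, convention=config.speed_convention
        )
        gamma_se = (
            gamma * fit.k_obs_se / fit.k_obs if fit.k_obs > 0 else 0.0
        )  # gamma is linear in k_obs
        try:
            d_py = degradation_percent(series, BENCHMARK_TIME_S)
        except ValueError:
            d_py = float("nan")
        try:
            y_1np = product_yield(series, "1-NP", BENCHMARK_TIME_S)
        except ValueError:
            y_1np = float("nan")
        records.append(
            SubstrateRecord(
                name=f"{series.substrate} @ {series.conditions.ppmv:g} ppmv",
                k_obs=fit.k_obs,
                k_obs_se=fit.k_obs_se,
                gamma=gamma,
                gamma_se=gamma_se,
                d_py=d_py,
                y_1np=y_1np,
                dnp_formed=dnp_flag(series),
            )
        )
        by_substrate.setdefault(series.substrate, []).append(
            (series.conditions.number_density, fit.k_obs, fit.k_obs_se)
        )

    write_substrate_table(records, outdir / "substrate_table.csv")

    mech_reports: dict[str, dict] = {}
    for substrate, triples in by_substrate.items():
        if len({c for c, _, _ in triples}) < 4:
            continue
        arr = np.array(sorted(triples))
        se = arr[:, 2]
        curve = RateCurve(
            substrate=substrate,
            concentrations=arr[:, 0],
            k_obs=arr[:, 1],
            k_obs_se=se if np.all(np.isfinite(se)) and np.all(se > 0) else None,
        )
        report = compare_mechanisms(
            curve,
            reference_ppbv=config.mechanism_ref_ppbv,
            temperature=config.temperature,
            pressure=config.pressure,
        )
        ambient = GasConditions.from_ppbv(
            config.ambient_ppbv, temperature=config.temperature, pressure=config.pressure
        )
        try:
            lh = fit_lh_no2(curve)
            k_amb, k_amb_se = predict_k_obs(lh, ambient.number_density)
            report["ambient_extrapolation"] = {
                "no2_ppbv": config.ambient_ppbv,
                "k_obs": k_amb,
                "k_obs_se": k_amb_se,
                "gamma": reaction_probability(
                    k_amb, PY_NO2, ambient, convention=config.speed_convention
                ),
                "lifetime_h": lifetime_hours(k_amb) if k_amb > 0 else float("inf"),
            }
        except Exception as exc:  # partial report on extrapolation failure
            report["ambient_extrapolation"] = {"error": str(exc)}
        mech_reports[substrate] = report

    with open(outdir / "mechanism_report.json", "w", encoding="utf-8") as fh:
        json.dump(mech_reports, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_provenance(config, outdir)
    return {"substrates": records, "mechanisms": mech_reports}


def run_field(config: RunConfig) -> dict:
    """Field CSV -> 1-NP/BkF dust-effect report (JSON + text)."""
    if config.field_csv is None:
        raise ValueError("run_field requires field_csv")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = read_field_csv(config.field_csv)
    report = dust_effect_report(df, coarse_cutoff=config.coarse_cutoff_um)
    with open(outdir / "field_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    (outdir / "field_report.txt").write_text(
        format_dust_report(report) + "\n", encoding="utf-8"
    )
    _write_provenance(config, outdir)
    return report


def run_synthesize(config: RunConfig) -> list[Path]:
    """Scenario file -> synthetic fixture CSVs.

    The scenario file (YAML or JSON) may contain ``decay`` (list of
    DecayScenario field dicts), ``rate_curves`` (list of dicts with model,
    k_max, K, concentrations_ppmv, noise_cv) and ``field`` (FieldScenario
    field dict). Scenario seeds default to the run seed when omitted. An
    empty scenario file writes nothing and succeeds.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec: dict = {}
    if config.scenario_file is not None:
        spec = yaml.safe_load(Path(config.scenario_file).read_text(encoding="utf-8")) or {}
    unknown = set(spec) - {"decay", "rate_curves", "field"}
    if unknown:
        raise ValueError(f"unknown scenario sections: {sorted(unknown)}")
    written: list[Path] = []

    decay_specs = spec.get("decay", [])
    if decay_specs:
        series = []
        for i, d in enumerate(decay_specs):
            d = dict(d)
            d.setdefault("seed", config.seed + i)
            if "times" in d:
                d["times"] = tuple(float(t) for t in d["times"])
            series.append(generate_decay_series(DecayScenario(**d)))
        path = outdir / "decay.csv"
        write_decay_csv(series, path)
        written.append(path)

    curve_specs = spec.get("rate_curves", [])
    if curve_specs:
        curves = []
        for i, c in enumerate(curve_specs):
            c = dict(c)
            ppmv = np.asarray(c.pop("concentrations_ppmv"), dtype=float)
            conc = [
                GasConditions.from_ppmv(
                    p, temperature=config.temperature, pressure=config.pressure
                ).number_density
                for p in ppmv
            ]
            c.setdefault("seed", config.seed + 100 + i)
            curves.append(generate_rate_curve(concentrations=conc, **c))
        path = outdir / "rate_curves.csv"
        write_rate_curve_csv(
            curves, path, temperature=config.temperature, pressure=config.pressure
        )
        written.append(path)

    if "field" in spec and spec["field"] is not None:
        f = dict(spec["field"])
        f.setdefault("seed", config.seed + 200)
        if "size_fractions_um" in f:
            f["size_fractions_um"] = tuple(
                (float(lo), float(hi)) for lo, hi in f["size_fractions_um"]
            )
        if "dust_period_indices" in f:
            f["dust_period_indices"] = tuple(int(i) for i in f["dust_period_indices"])
        df = generate_field_dataset(FieldScenario(**f))
        path = outdir / "field.csv"
        write_field_csv(df, path)
        written.append(path)

    _write_provenance(config, outdir)
    return written
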