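"""Synthetic flow-reactor and field-campaign data with known ground truth.

The generators emulate the three kinds of measurement the analysis consumes:

* pyrene decay time series on a substrate under constant NO2 (plateau-shifted
  exponential truth, multiplicative Gaussian replicate noise, optional 1-NP /
  DNP product tracks from a consecutive first-order scheme);
* k_obs-vs-[NO2] rate curves from either saturating mechanism;
* cascade-impactor tables of size-fractionated 1-NP and BkF concentrations
  over sampling periods, with a configurable dust-storm enhancement of the
  1-NP/BkF ratio confined to coarse fractions.

Noise is multiplicative and CV-parameterized throughout (chromatographic
quantification error scales with signal). Every generator is a pure function
of its scenario, whose ``seed`` drives a single top-level
``numpy.random.SeedSequence``; per-stream children are spawned
deterministically, so fixed seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_units import GasConditions
from .decay_kinetics import DecaySeries
from .mechanism_fitting import RateCurve

__all__ = [
    "DecayScenario",
    "FieldScenario",
    "DEFAULT_TIMES_S",
    "DEFAULT_SIZE_FRACTIONS_UM",
    "generate_decay_series",
    "generate_rate_curve",
    "generate_field_dataset",
]

#: Default exposure-time grid, s: 0-4 h plus the 2 h benchmark point.
DEFAULT_TIMES_S: tuple[float, ...] = (0.0, 600.0, 1800.0, 3600.0, 7200.0, 10800.0, 14400.0)

#: Five-stage cascade-impactor aerodynamic-diameter bounds, um
#: (>7.0, 3.3-7.0, 2.0-3.3, 1.1-2.0, <=1.1).
DEFAULT_SIZE_FRACTIONS_UM: tuple[tuple[float, float], ...] = (
    (7.0, float("inf")),
    (3.3, 7.0),
    (2.0, 3.3),
    (1.1, 2.0),
    (0.0, 1.1),
)


@dataclass(frozen=True)
class DecayScenario:
    """Ground truth for one synthetic decay experiment.

    Defaults mirror the bench conditions of the flow-reactor survey: 3 ppmv
    NO2, triplicate runs, 5% multiplicative noise, and a desert-dust-like
    rate constant; a 7200 s (2 h) point is always present so benchmark
    degradation summaries apply.
    """

    k_true: float = 8.6e-4  # s^-1, desert-dust-like
    plateau_true: float = 0.0
    times: tuple[float, ...] = DEFAULT_TIMES_S
    replicates: int = 3
    noise_cv: float = 0.05
    seed: int = 0
    substrate: str = "synthetic-dust"
    no2_ppmv: float = 3.0
    with_products: bool = False
    product_branching: float = 0.6  # mole fraction of reacted Py going to 1-NP
    k_secondary: Optional[float] = None  # 1-NP -> DNP rate; default k_true / 5

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0.0 <= self.plateau_true < 1.0):
            raise ValueError("plateau_true must lie in [0, 1)")
        if 7200.0 not in self.times:
            raise ValueError("the time grid must include the 7200 s benchmark point")


@dataclass(frozen=True)
class FieldScenario:
    """Ground truth for a synthetic impactor field campaign.

    ``dust_enhancement`` multiplies the 1-NP/BkF ratio only in size fractions
    whose lower bound is at or above ``coarse_cutoff_um``, and only during
    heavy-dust periods — the signature of mineral-dust-driven nitration.
    """

    n_periods: int = 12
    dust_period_indices: tuple[int, ...] = (4, 5, 6)
    size_fractions_um: tuple[tuple[float, float], ...] = DEFAULT_SIZE_FRACTIONS_UM
    baseline_bkf: float = 30.0  # pg m^-3, median BkF per fraction
    baseline_ratio: float = 0.2  # 1-NP/BkF with no dust chemistry
    dust_enhancement: float = 5.0
    coarse_cutoff_um: float = 2.0
    lognormal_sigma: float = 0.3
    period_days: int = 2
    start_date: str = "2010-03-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dust_enhancement < 1.0:
            raise ValueError("dust_enhancement must be >= 1")
        if any(i >= self.n_periods for i in self.dust_period_indices):
            raise ValueError("dust_period_indices out of range")


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _plateau_decay(t: np.ndarray, k: float, p: float) -> np.ndarray:
    return p + (1.0 - p) * np.exp(-k * t)


def _consecutive_products(
    t: np.ndarray, k1: float, k2: float, reactive: float, branching: float
) -> tuple[np.ndarray, np.ndarray]:
    """1-NP and DNP mole fractions from Py -> 1-NP -> DNP with branching
    ``branching`` of the reactive pyrene pool entering the nitro channel."""
    if abs(k2 - k1) < 1e-12 * max(k1, k2, 1e-30):
        k2 = k1 * (1.0 + 1e-6)  # regularize the degenerate equal-rate case
    onp = branching * reactive * k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    reacted = branching * reactive * (1.0 - np.exp(-k1 * t))
    dnp = reacted - onp
    return np.clip(onp, 0.0, None), np.clip(dnp, 0.0, None)


def generate_decay_series(scenario: DecayScenario) -> DecaySeries:
    """Synthesize one replicated decay series from a plateau-shifted truth.

    py_fraction = [p + (1-p) exp(-k t)] * (1 + eps), eps ~ N(0, noise_cv),
    clipped at 0. Product tracks (if requested) get the same noise model.
    """
    rng_decay, rng_prod = _child_rngs(scenario.seed, 2)
    t = np.asarray(scenario.times, dtype=float)
    clean = _plateau_decay(t, scenario.k_true, scenario.plateau_true)
    points = []
    for rep in range(scenario.replicates):
        eps = rng_decay.normal(0.0, scenario.noise_cv, size=len(t)) if scenario.noise_cv else 0.0
        noisy = np.clip(clean * (1.0 + eps), 0.0, None)
        points.extend((float(tt), float(ff), f"r{rep + 1}") for tt, ff in zip(t, noisy))
    product_points: list[tuple[float, str, float, str]] = []
    if scenario.with_products:
        k2 = scenario.k_secondary if scenario.k_secondary is not None else scenario.k_true / 5.0
        onp, dnp = _consecutive_products(
            t, scenario.k_true, k2, 1.0 - scenario.plateau_true, scenario.product_branching
        )
        for rep in range(scenario.replicates):
            for species, clean_y in (("1-NP", onp), ("DNP", dnp)):
                eps = (
                    rng_prod.normal(0.0, scenario.noise_cv, size=len(t))
                    if scenario.noise_cv
                    else 0.0
                )
                noisy = np.clip(clean_y * (1.0 + eps), 0.0, None)
                product_points.extend(
                    (float(tt), species, float(yy), f"r{rep + 1}")
                    for tt, yy in zip(t, noisy)
                )
    return DecaySeries(
        substrate=scenario.substrate,
        conditions=GasConditions.from_ppmv(scenario.no2_ppmv),
        points=points,
        product_points=product_points,
    )


def generate_rate_curve(
    model: str,
    k_max: float,
    K: float,
    concentrations: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    substrate: str = "synthetic-dust",
) -> RateCurve:
    """Synthesize a k_obs-vs-concentration curve from a mechanism truth.

    ``model`` is "LH_NO2" (k = k_max K c / (1 + K c)) or "N2O4"
    (k = k_max K' c^2 / (1 + K' c^2)); concentrations are number densities in
    molecules m^-3. Noise is multiplicative Gaussian with CV ``noise_cv`` and
    the SE column is set to k_obs * noise_cv (zero noise leaves SEs unset).
    """
    if model not in ("LH_NO2", "N2O4"):
        raise ValueError(f"unknown mechanism model {model!r}")
    c = np.asarray(concentrations, dtype=float)
    x = c * c if model == "N2O4" else c
    clean = k_max * K * x / (1.0 + K * x)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if noise_cv > 0:
        k = np.clip(clean * (1.0 + rng.normal(0.0, noise_cv, size=len(c))), 1e-30, None)
        se = k * noise_cv
    else:
        k, se = clean, None
    return RateCurve(substrate=substrate, concentrations=c, k_obs=k, k_obs_se=se)


def generate_field_dataset(scenario: FieldScenario) -> pd.DataFrame:
    """Synthesize a size-fractionated 1-NP / BkF impactor table.

    Per period x fraction: BkF ~ lognormal about the baseline; 1-NP = BkF x
    baseline ratio x (dust enhancement if the period is a heavy-dust one AND
    the fraction is coarse) x independent lognormal noise. Columns match the
    field CSV dialect (period_start, period_end, fraction_lo_um,
    fraction_hi_um, conc_1np, conc_bkf, dust_label).
    """
    rng_bkf, rng_ratio = _child_rngs(scenario.seed, 2)
    start = pd.Timestamp(scenario.start_date)
    sigma = scenario.lognormal_sigma
    rows = []
    for i in range(scenario.n_periods):
        p_start = start + pd.Timedelta(days=i * scenario.period_days)
        p_end = p_start + pd.Timedelta(days=scenario.period_days)
        heavy = i in scenario.dust_period_indices
        label = "heavy" if heavy else ("low" if i % 2 == 0 else "none")
        for lo, hi in scenario.size_fractions_um:
            coarse = lo >= scenario.coarse_cutoff_um
            bkf = scenario.baseline_bkf * rng_bkf.lognormal(0.0, sigma)
            ratio = scenario.baseline_ratio * rng_ratio.lognormal(0.0, sigma)
            if heavy and coarse:
                ratio *= scenario.dust_enhancement
            rows.append(
                {
                    "period_start": p_start.date().isoformat(),
                    "period_end": p_end.date().isoformat(),
                    "fraction_lo_um": lo,
                    "fraction_hi_um": hi,
                    "conc_1np": bkf * ratio,
                    "conc_bkf": bkf,
                    "dust_label": label,
                }
            )
    return pd.DataFrame(rows)
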