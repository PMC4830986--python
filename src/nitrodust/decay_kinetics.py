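"""Pseudo-first-order decay fitting for surface-bound pyrene under NO2.

A :class:`DecaySeries` holds the fraction of pyrene remaining,
``[Py]_t / [Py]_0``, at a set of exposure times (replicates kept as
individual points). Two nested models are fitted by nonlinear least squares:

* simple first order,      f(t) = exp(-k_obs t)
* plateau-shifted first order, f(t) = p + (1 - p) exp(-k_obs t), 0 <= p < 1

where p is the residual unreactive fraction ``[Py]_plateau / [Py]_0``.
:func:`select_decay_model` chooses between them with an extra-sum-of-squares
F-test at alpha = 0.05. Summaries mirror the usual bench-top reporting:
percent pyrene degraded and nitro-product yields at a benchmark exposure
time, and a presence/absence flag for dinitropyrenes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import (
    BENCHMARK_TIME_S,
    DNP_DETECTION_THRESHOLD,
    DNP_FLAG_TIME_S,
)
from .core_units import GasConditions

__all__ = [
    "DecaySeries",
    "KineticsFit",
    "FitFailure",
    "fit_simple_decay",
    "fit_plateau_decay",
    "select_decay_model",
    "degradation_percent",
    "product_yield",
    "dnp_flag",
    "read_decay_csv",
    "write_decay_csv",
    "read_products_csv",
]

DECAY_CSV_COLUMNS = ["substrate", "no2_ppmv", "time_s", "py_fraction", "replicate"]
PRODUCT_CSV_COLUMNS = ["substrate", "time_s", "species", "yield_fraction", "replicate"]

_SELECTION_ALPHA = 0.05
_PLATEAU_UPPER = 1.0 - 1e-9


class FitFailure(RuntimeError):
    """Raised when a nonlinear least-squares fit does not converge.

    Carries the optimizer diagnostics in ``args[0]``.
    """


@dataclass
class DecaySeries:
    """Time series of the pyrene fraction remaining for one substrate/condition.

    ``points`` is a list of ``(time_s, py_fraction, replicate)`` tuples;
    ``product_points`` optionally holds ``(time_s, species, yield_fraction,
    replicate)`` for reaction products ("1-NP", "DNP").
    """

    substrate: str
    conditions: Optional[GasConditions] = None
    points: list[tuple[float, float, str]] = field(default_factory=list)
    product_points: list[tuple[float, str, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.times
        f = self.fractions
        if np.any(t < 0):
            raise ValueError("exposure times must be >= 0 s")
        if len(np.unique(t)) < 3:
            raise ValueError(
                f"a decay series needs >= 3 distinct times, got {len(np.unique(t))}"
            )
        if not np.all(np.isfinite(f)):
            raise ValueError("py_fraction values must be finite")
        if np.any(f > 1.0 + 1e-12):
            warnings.warn(
                f"{self.substrate}: py_fraction above 1 (max {f.max():.3g}); "
                "treating as measurement noise",
                stacklevel=2,
            )

    @property
    def times(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.points], dtype=float)

    @property
    def fractions(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.points], dtype=float)

    @property
    def n_distinct_times(self) -> int:
        return len(np.unique(self.times))


@dataclass
class KineticsFit:
    """Result of a pseudo-first-order decay fit.

    ``plateau`` is fixed at 0 for the simple model. ``plateau_pinned`` flags a
    plateau estimate stuck at a bound of [0, 1). When produced by
    :func:`select_decay_model`, ``selected`` names the winning model and
    ``f_pvalue`` the extra-sum-of-squares test p-value.
    """

    k_obs: float
    k_obs_se: float
    plateau: float
    plateau_se: float
    model: str  # "simple" | "plateau"
    rss: float
    n_points: int
    plateau_pinned: bool = False
    f_pvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k_obs < 0:
            raise ValueError(f"k_obs must be >= 0 s^-1, got {self.k_obs}")
        if not (0.0 <= self.plateau < 1.0):
            raise ValueError(f"plateau fraction must lie in [0, 1), got {self.plateau}")


def _normalized(series: DecaySeries, normalize: bool) -> tuple[np.ndarray, np.ndarray]:
    t = series.times
    f = series.fractions
    if normalize:
        t0 = t.min()
        f0 = f[t == t0].mean()
        if f0 <= 0:
            raise ValueError("cannot normalize: mean fraction at the first time is <= 0")
        f = f / f0
    return t, f


def _k_start(t: np.ndarray, f: np.ndarray) -> float:
    # ln(first/last) over the spanned time, floored so the optimizer can move
    order = np.argsort(t)
    f_first = max(f[order][0], 1e-12)
    f_last = max(f[order][-1], 1e-12)
    span = t.max() - t.min()
    if span <= 0 or f_last >= f_first:
        return 1e-8
    return max(np.log(f_first / f_last) / span, 1e-8)


def fit_simple_decay(series: DecaySeries, normalize: bool = False) -> KineticsFit:
    """Fit f(t) = exp(-k_obs t) by Levenberg-Marquardt least squares.

    All replicate points enter unweighted. The standard error is the usual
    asymptotic one from the Jacobian-based covariance scaled by the residual
    variance. All-constant data return k_obs = 0 with a warning.
    """
    t, f = _normalized(series, normalize)
    if np.ptp(f) == 0.0:
        warnings.warn(
            f"{series.substrate}: all fractions identical; returning k_obs = 0",
            stacklevel=2,
        )
        rss = float(np.sum((f - 1.0) ** 2))  # residuals about the k=0 model
        return KineticsFit(0.0, 0.0, 0.0, 0.0, "simple", rss, len(t))

    def model(tt, k):
        return np.exp(-k * tt)

    try:
        popt, pcov = optimize.curve_fit(
            model, t, f, p0=[_k_start(t, f)], method="lm", maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - rare optimizer failure
        raise FitFailure(f"simple decay fit failed for {series.substrate}: {exc}") from exc
    k = float(abs(popt[0]))  # the model is even in k only at k=0; abs guards -0.0
    resid = f - model(t, k)
    rss = float(resid @ resid)
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    return KineticsFit(k, se, 0.0, 0.0, "simple", rss, len(t))


def fit_plateau_decay(series: DecaySeries, normalize: bool = False) -> KineticsFit:
    """Fit f(t) = p + (1 - p) exp(-k_obs t) with p constrained to [0, 1).

    Uses bounded trust-region least squares (the bound on p rules out plain
    Levenberg-Marquardt). A plateau estimate pinned at a bound is flagged in
    the result rather than raised.
    """
    if series.n_distinct_times < 4:
        raise ValueError(
            "plateau fit needs >= 4 distinct times "
            f"(got {series.n_distinct_times}); use fit_simple_decay"
        )
    t, f = _normalized(series, normalize)

    def model(tt, k, p):
        return p + (1.0 - p) * np.exp(-k * tt)

    p0 = [_k_start(t, f), float(np.clip(f.min(), 0.0, 0.99))]
    try:
        popt, pcov = optimize.curve_fit(
            model,
            t,
            f,
            p0=p0,
            bounds=([0.0, 0.0], [np.inf, _PLATEAU_UPPER]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitFailure(f"plateau decay fit failed for {series.substrate}: {exc}") from exc
    k, p = float(popt[0]), float(popt[1])
    resid = f - model(t, k, p)
    rss = float(resid @ resid)
    ses = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    pinned = bool(p <= 1e-7 or p >= _PLATEAU_UPPER - 1e-7)
    if pinned:
        warnings.warn(
            f"{series.substrate}: plateau estimate pinned at bound (p = {p:.3g})",
            stacklevel=2,
        )
    return KineticsFit(
        k,
        float(ses[0]) if np.isfinite(ses[0]) else np.inf,
        min(p, _PLATEAU_UPPER - 1e-12),
        float(ses[1]) if np.isfinite(ses[1]) else np.inf,
        "plateau",
        rss,
        len(t),
        plateau_pinned=pinned,
    )


def select_decay_model(
    series: DecaySeries, normalize: bool = False, alpha: float = _SELECTION_ALPHA
) -> KineticsFit:
    """Fit both decay models and keep the plateau one only if it earns it.

    The extra-sum-of-squares F-test compares the nested models; the plateau
    model is returned iff its improvement is significant at ``alpha``. With
    fewer than 4 distinct times the simple model is forced (no residual
    degrees of freedom for the extra parameter).
    """
    simple = fit_simple_decay(series, normalize=normalize)
    if series.n_distinct_times < 4:
        warnings.warn(
            f"{series.substrate}: only {series.n_distinct_times} distinct times; "
            "simple model forced",
            stacklevel=2,
        )
        simple.f_pvalue = None
        return simple
    plateau = fit_plateau_decay(series, normalize=normalize)
    n = plateau.n_points
    dof = n - 2
    if dof <= 0:
        simple.f_pvalue = None
        return simple
    if plateau.rss <= 1e-30:
        # Noiseless nested fits: keep the extra parameter only if it moved
        pvalue = 0.0 if simple.rss > 1e-24 else 1.0
    else:
        f_stat = max(simple.rss - plateau.rss, 0.0) / (plateau.rss / dof)
        pvalue = float(stats.f.sf(f_stat, 1, dof))
    winner = plateau if pvalue < alpha else simple
    winner.f_pvalue = pvalue
    return winner


def degradation_percent(series: DecaySeries, t: float = BENCHMARK_TIME_S) -> float:
    """Percent of pyrene degraded at exposure time ``t`` (exact-match lookup).

    D = (1 - mean fraction remaining at t) * 100. Replicates at t are
    averaged; a missing observation is an error — no interpolation.
    """
    times = series.times
    mask = np.isclose(times, t, rtol=1e-9, atol=1e-6)
    if not mask.any():
        raise ValueError(
            f"{series.substrate}: no observation at t = {t} s "
            f"(available: {sorted(set(times))}); refusing to interpolate"
        )
    return float((1.0 - series.fractions[mask].mean()) * 100.0)


def _product_mask(series: DecaySeries, species: str, t: float) -> np.ndarray:
    pts = series.product_points
    if not pts:
        raise ValueError(f"{series.substrate}: series has no product measurements")
    avail = sorted({p[1] for p in pts})
    if species not in avail:
        raise ValueError(
            f"{series.substrate}: no product species {species!r}; available: {avail}"
        )
    times = np.asarray([p[0] for p in pts], dtype=float)
    names = np.asarray([p[1] for p in pts])
    return (names == species) & np.isclose(times, t, rtol=1e-9, atol=1e-6)


def product_yield(series: DecaySeries, species: str, t: float = BENCHMARK_TIME_S) -> float:
    """Product yield at time ``t`` in percent of the initial pyrene (mol/mol)."""
    mask = _product_mask(series, species, t)
    if not mask.any():
        raise ValueError(
            f"{series.substrate}: no {species} observation at t = {t} s"
        )
    fracs = np.asarray([p[2] for p in series.product_points], dtype=float)
    return float(fracs[mask].mean() * 100.0)


def dnp_flag(
    series: DecaySeries,
    t: float = DNP_FLAG_TIME_S,
    threshold: float = DNP_DETECTION_THRESHOLD,
) -> str:
    """Dinitropyrene presence flag: "+" if the DNP yield at ``t`` exceeds the
    detection threshold (default 0.5% of initial pyrene), else "-"."""
    try:
        mask = _product_mask(series, "DNP", t)
    except ValueError:
        return "-"
    if not mask.any():
        return "-"
    fracs = np.asarray([p[2] for p in series.product_points], dtype=float)
    return "+" if fracs[mask].mean() > threshold else "-"


# ---------------------------------------------------------------------------
# CSV interface (comma-separated, UTF-8, "." decimal)

def write_decay_csv(series_list: Iterable[DecaySeries], path) -> None:
    rows = []
    for s in series_list:
        ppmv = s.conditions.ppmv if s.conditions is not None else np.nan
        for t, f, rep in s.points:
            rows.append((s.substrate, ppmv, t, f, rep))
    # %.17g keeps the round trip lossless at double precision
    pd.DataFrame(rows, columns=DECAY_CSV_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_decay_csv(
    path, temperature: float | None = None, pressure: float | None = None
) -> list[DecaySeries]:
    """Read decay CSV (columns substrate,no2_ppmv,time_s,py_fraction,replicate)
    into one :class:`DecaySeries` per (substrate, NO2 level)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(DECAY_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"decay CSV {path} missing columns: {sorted(missing)}")
    kwargs = {}
    if temperature is not None:
        kwargs["temperature"] = temperature
    if pressure is not None:
        kwargs["pressure"] = pressure
    out = []
    for (substrate, ppmv), grp in df.groupby(["substrate", "no2_ppmv"], sort=True):
        cond = GasConditions.from_ppmv(float(ppmv), **kwargs)
        pts = [
            (float(r.time_s), float(r.py_fraction), str(r.replicate))
            for r in grp.itertuples()
        ]
        out.append(DecaySeries(substrate=str(substrate), conditions=cond, points=pts))
    return out


def read_products_csv(path) -> dict[str, list[tuple[float, str, float, str]]]:
    """Read product-yield CSV; returns {substrate: [(t, species, yield, rep)]}."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(PRODUCT_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"product CSV {path} missing columns: {sorted(missing)}")
    out: dict[str, list[tuple[float, str, float, str]]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.substrate), []).append(
            (float(r.time_s), str(r.species), float(r.yield_fraction), str(r.replicate))
        )
    return out
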