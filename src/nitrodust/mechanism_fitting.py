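"""Langmuir-Hinshelwood vs N2O4-route fits of k_obs against gas-phase NO2.

Two saturating mechanisms are fitted to (concentration, k_obs) curves:

* ``LH_NO2`` — surface reaction with adsorbed NO2 in gas-surface
  partitioning equilibrium: k_obs(c) = k_max K c / (1 + K c), first order in
  NO2 at low concentration (K c << 1), zeroth order at high (K c >> 1).
* ``N2O4`` — reaction via surface-adsorbed N2O4 whose gas-phase precursor
  scales as [NO2]^2 (dimerization equilibrium), lumping the dimerization and
  gas-to-surface constants into K': k_obs(c) = k_max K' c^2 / (1 + K' c^2),
  second order at low concentration.

Fits run in number-density units (molecules m^-3) so K has its physical
gas-to-surface meaning; ppmv appears only in the CSV reader. Discrimination
uses the small-sample-corrected Akaike criterion (AICc) plus the ratio of
the two predictions at a low reference concentration (default 100 ppbv),
where the quadratic model falls well below the hyperbolic one whenever the
data were generated by surface-NO2 chemistry.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize

from .constants import MECHANISM_REF_PPBV
from .core_units import mixing_ratio_to_number_density
from .decay_kinetics import FitFailure

__all__ = [
    "RateCurve",
    "MechanismFit",
    "fit_lh_no2",
    "fit_n2o4",
    "predict_k_obs",
    "apparent_reaction_order",
    "compare_mechanisms",
    "read_rate_curve_csv",
    "write_rate_curve_csv",
    "write_comparison_json",
]

RATE_CSV_COLUMNS = ["substrate", "no2_ppmv", "k_obs_s", "k_obs_se"]


@dataclass
class RateCurve:
    """k_obs as a function of gas-phase NO2 number density for one substrate."""

    substrate: str
    concentrations: np.ndarray  # molecules m^-3
    k_obs: np.ndarray  # s^-1
    k_obs_se: Optional[np.ndarray] = None  # s^-1, used as fit weights if all > 0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.k_obs = np.asarray(self.k_obs, dtype=float)
        if self.k_obs_se is not None:
            self.k_obs_se = np.asarray(self.k_obs_se, dtype=float)
        if np.any(self.concentrations <= 0):
            raise ValueError("NO2 number densities must be > 0")
        if len(np.unique(self.concentrations)) < 3:
            raise ValueError(
                "a rate curve needs >= 3 distinct concentrations for a "
                "2-parameter mechanism fit"
            )

    @property
    def weights(self) -> Optional[np.ndarray]:
        se = self.k_obs_se
        if se is not None and np.all(np.isfinite(se)) and np.all(se > 0):
            return se
        return None


@dataclass
class MechanismFit:
    """Fitted saturating mechanism: model label, k_max, K, and covariance.

    For ``LH_NO2`` K is the NO2 gas-to-surface equilibrium constant (m^3);
    for ``N2O4`` K is the lumped K' = K_dimerization * K_gas-to-surface (m^6).
    """

    model: str  # "LH_NO2" | "N2O4"
    k_max: float
    K: float
    covariance: np.ndarray
    rss: float
    n_points: int
    aicc: float = field(init=False)

    def __post_init__(self) -> None:
        if self.model not in ("LH_NO2", "N2O4"):
            raise ValueError(f"unknown mechanism model {self.model!r}")
        if not (self.k_max > 0 and self.K > 0):
            raise FitFailure(
                f"{self.model} fit returned non-positive parameters "
                f"(k_max={self.k_max:.3g}, K={self.K:.3g})"
            )
        C = np.asarray(self.covariance, dtype=float)
        if C.shape != (2, 2):
            raise ValueError("covariance must be 2x2")
        if not np.allclose(C, C.T, rtol=1e-8, atol=0):
            raise ValueError("covariance must be symmetric")
        self.covariance = 0.5 * (C + C.T)
        self.aicc = _aicc(self.rss, self.n_points, n_params=2)

    @property
    def k_max_se(self) -> float:
        return float(np.sqrt(max(self.covariance[0, 0], 0.0)))

    @property
    def K_se(self) -> float:
        return float(np.sqrt(max(self.covariance[1, 1], 0.0)))

    def _x(self, c: np.ndarray | float) -> np.ndarray | float:
        return c * c if self.model == "N2O4" else c


def _aicc(rss: float, n: int, n_params: int) -> float:
    # Gaussian-likelihood AIC with the small-sample correction
    if n <= n_params + 1:
        return math.inf
    rss = max(rss, 1e-300)
    return (
        n * math.log(rss / n)
        + 2 * n_params
        + 2 * n_params * (n_params + 1) / (n - n_params - 1)
    )


def _saturating(x, k_max, K):
    Kx = K * x
    return k_max * Kx / (1.0 + Kx)


def _fit_mechanism(curve: RateCurve, model: str) -> MechanismFit:
    c = curve.concentrations
    x = c * c if model == "N2O4" else c
    k = curve.k_obs
    k_max0 = 1.2 * float(k.max())
    # K from the half-saturation point, located by linear interpolation of
    # k_obs against the (possibly squared) concentration axis
    order = np.argsort(x)
    xs, ks = x[order], k[order]
    half = k_max0 / 2.0
    above = np.nonzero(ks >= half)[0]
    if len(above) and above[0] > 0:
        i = above[0]
        frac = (half - ks[i - 1]) / (ks[i] - ks[i - 1])
        x_half = xs[i - 1] + frac * (xs[i] - xs[i - 1])
    else:
        x_half = xs[len(xs) // 2]
    K0 = 1.0 / max(x_half, 1e-300)
    sigma = curve.weights

    # k_max (~1e-3 s^-1) and K (~1e-20 m^3 or ~1e-40 m^6) live tens of orders
    # of magnitude apart, which defeats finite-difference steps in the raw
    # parameters; fitting log-parameters conditions the problem and enforces
    # positivity, and Levenberg-Marquardt then converges from the
    # half-saturation start.
    def residuals(logp: np.ndarray) -> np.ndarray:
        r = _saturating(x, math.exp(logp[0]), math.exp(logp[1])) - k
        return r / sigma if sigma is not None else r

    res = optimize.least_squares(
        residuals,
        x0=[math.log(k_max0), math.log(K0)],
        method="lm",
        max_nfev=20000,
    )
    if not res.success or not np.all(np.isfinite(res.x)):
        raise FitFailure(
            f"{model} fit failed for {curve.substrate}: {res.message} "
            f"(status {res.status})"
        )
    k_max, K = math.exp(res.x[0]), math.exp(res.x[1])
    resid = k - _saturating(x, k_max, K)
    rss = float(resid @ resid)
    dof = len(k) - 2
    # asymptotic covariance in log space, scaled by the residual variance,
    # then mapped back through d(param)/d(log param) = param
    jtj = res.jac.T @ res.jac
    s2 = 2.0 * res.cost / dof if dof > 0 else np.nan
    try:
        cov_log = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        cov_log = np.linalg.pinv(jtj) * s2
    if not np.all(np.isfinite(cov_log)):
        warnings.warn(
            f"{curve.substrate}: ill-conditioned {model} fit, covariance not finite",
            stacklevel=3,
        )
        cov_log = np.diag([np.inf, np.inf])
    D = np.diag([k_max, K])
    pcov = D @ cov_log @ D
    return MechanismFit(
        model=model,
        k_max=k_max,
        K=K,
        covariance=np.asarray(pcov),
        rss=rss,
        n_points=len(k),
    )


def fit_lh_no2(curve: RateCurve) -> MechanismFit:
    """Fit the Langmuir-Hinshelwood (adsorbed-NO2) model
    k_obs = k_max K c / (1 + K c)."""
    return _fit_mechanism(curve, "LH_NO2")


def fit_n2o4(curve: RateCurve) -> MechanismFit:
    """Fit the N2O4-route model k_obs = k_max K' c^2 / (1 + K' c^2)."""
    return _fit_mechanism(curve, "N2O4")


def predict_k_obs(fit: MechanismFit, c: float) -> tuple[float, float]:
    """Model prediction at NO2 number density ``c`` with a delta-method SE.

    The SE propagates the full 2x2 parameter covariance through the gradient
    (dk/dk_max, dk/dK); both models vanish at c = 0 with zero SE and saturate
    at k_max as c grows.
    """
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    x = fit._x(float(c))
    Kx = fit.K * x
    value = fit.k_max * Kx / (1.0 + Kx)
    grad = np.array(
        [Kx / (1.0 + Kx), fit.k_max * x / (1.0 + Kx) ** 2]
    )
    var = float(grad @ fit.covariance @ grad)
    return float(value), math.sqrt(max(var, 0.0))


def apparent_reaction_order(fit: MechanismFit, c: float) -> float:
    """Local reaction order d ln k_obs / d ln c, evaluated analytically.

    LH_NO2: 1 / (1 + K c)  (1 at low c, 0 at saturation);
    N2O4:   2 / (1 + K' c^2)  (2 at low c, 0 at saturation).
    """
    if c <= 0:
        raise ValueError(f"concentration must be > 0, got {c}")
    if fit.model == "N2O4":
        return 2.0 / (1.0 + fit.K * c * c)
    return 1.0 / (1.0 + fit.K * c)


def compare_mechanisms(
    curve: RateCurve, reference_ppbv: float = MECHANISM_REF_PPBV,
    temperature: float | None = None, pressure: float | None = None,
) -> dict:
    """Fit both mechanisms and report how they separate at low concentration.

    Returns a JSON-ready dict with per-model parameters, SEs, covariance,
    RSS and AICc, the predictions at the reference concentration (default
    100 ppbv), their N2O4/LH ratio, and the AICc-preferred model. A failed
    fit is recorded in the report instead of aborting the comparison.
    """
    if len(np.unique(curve.concentrations)) < 4:
        raise ValueError("mechanism comparison needs >= 4 distinct concentrations")
    kwargs = {}
    if temperature is not None:
        kwargs["temperature"] = temperature
    if pressure is not None:
        kwargs["pressure"] = pressure
    c_ref = mixing_ratio_to_number_density(reference_ppbv * 1e-9, **kwargs)
    report: dict = {
        "substrate": curve.substrate,
        "reference_ppbv": reference_ppbv,
        "reference_number_density_m3": c_ref,
        "models": {},
    }
    for name, fitter in (("LH_NO2", fit_lh_no2), ("N2O4", fit_n2o4)):
        try:
            fit = fitter(curve)
        except (FitFailure, ValueError) as exc:
            report["models"][name] = {"error": str(exc)}
            continue
        pred, pred_se = predict_k_obs(fit, c_ref)
        report["models"][name] = {
            "params": {"k_max": fit.k_max, "K": fit.K},
            "se": {"k_max": fit.k_max_se, "K": fit.K_se},
            "covariance": fit.covariance.tolist(),
            "rss": fit.rss,
            "aicc": fit.aicc,
            "pred_at_ref": pred,
            "pred_at_ref_se": pred_se,
        }
    ok = {m: r for m, r in report["models"].items() if "error" not in r}
    if len(ok) == 2:
        report["pred_ratio_n2o4_over_lh"] = (
            ok["N2O4"]["pred_at_ref"] / ok["LH_NO2"]["pred_at_ref"]
            if ok["LH_NO2"]["pred_at_ref"] > 0
            else math.inf
        )
        report["preferred_by_aicc"] = min(ok, key=lambda m: ok[m]["aicc"])
    elif len(ok) == 1:
        report["preferred_by_aicc"] = next(iter(ok))
    else:
        report["preferred_by_aicc"] = None
    return report


# ---------------------------------------------------------------------------
# CSV / JSON interface

def write_rate_curve_csv(
    curves: list[RateCurve], path,
    temperature: float | None = None, pressure: float | None = None,
) -> None:
    kwargs = {}
    if temperature is not None:
        kwargs["temperature"] = temperature
    if pressure is not None:
        kwargs["pressure"] = pressure
    per_unit = mixing_ratio_to_number_density(1e-6, **kwargs)  # density per ppmv
    rows = []
    for cur in curves:
        se = cur.k_obs_se if cur.k_obs_se is not None else np.full(len(cur.k_obs), np.nan)
        for c, k, s in zip(cur.concentrations, cur.k_obs, se):
            rows.append((cur.substrate, c / per_unit, k, s))
    pd.DataFrame(rows, columns=RATE_CSV_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_rate_curve_csv(
    path, temperature: float | None = None, pressure: float | None = None
) -> list[RateCurve]:
    """Read rate-curve CSV (substrate,no2_ppmv,k_obs_s,k_obs_se); mixing
    ratios are converted to number densities at the stated T, P."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(RATE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"rate-curve CSV {path} missing columns: {sorted(missing)}")
    kwargs = {}
    if temperature is not None:
        kwargs["temperature"] = temperature
    if pressure is not None:
        kwargs["pressure"] = pressure
    per_unit = mixing_ratio_to_number_density(1e-6, **kwargs)
    out = []
    for substrate, grp in df.groupby("substrate", sort=True):
        se = grp["k_obs_se"].to_numpy(dtype=float)
        out.append(
            RateCurve(
                substrate=str(substrate),
                concentrations=grp["no2_ppmv"].to_numpy(dtype=float) * per_unit,
                k_obs=grp["k_obs_s"].to_numpy(dtype=float),
                k_obs_se=None if np.all(np.isnan(se)) else se,
            )
        )
    return out


def write_comparison_json(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
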