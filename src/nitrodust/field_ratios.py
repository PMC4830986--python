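"""Size-fractionated 1-NP/BkF ratio analysis for dust-storm field data.

The 1-NP/BkF ratio — 1-nitropyrene over benzo[k]fluoranthene, an unreactive
non-volatile reference PAH — is source-invariant: if both species come only
from combustion sources it stays constant, so an increase flags secondary
(on-particle) 1-NP formation. This module computes the ratio per impactor
size fraction, classifies sampling periods by dust load, and tests heavy-dust
vs non-/low-dust periods with a Mann-Whitney U test that is exact (full
enumeration of labelings) for small untied samples and a tie- and
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import COARSE_CUTOFF_UM

__all__ = [
    "FieldSample",
    "ratio_1np_bkf",
    "classify_periods",
    "mann_whitney_u",
    "dust_effect_report",
    "format_dust_report",
    "read_field_csv",
    "write_field_csv",
]

logger = logging.getLogger(__name__)

FIELD_CSV_COLUMNS = [
    "period_start", "period_end", "fraction_lo_um", "fraction_hi_um",
    "conc_1np", "conc_bkf", "dust_label",
]

#: Largest pooled sample size for which the exact null distribution of U is
#: enumerated (C(12, 6) = 924 labelings at worst).
EXACT_ENUMERATION_LIMIT = 12


@dataclass
class FieldSample:
    """One impactor stage in one sampling period."""

    period_start: str
    period_end: str
    fraction_lo_um: float
    fraction_hi_um: float
    conc_1np: float
    conc_bkf: float
    dust_label: str = "none"  # heavy | low | none
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.conc_1np < 0 or self.conc_bkf < 0:
            raise ValueError("concentrations must be >= 0")


def ratio_1np_bkf(sample: FieldSample) -> float:
    """1-NP/BkF concentration ratio; NaN (never infinity) when BkF is absent."""
    if sample.conc_bkf > 0:
        return sample.conc_1np / sample.conc_bkf
    return math.nan


def classify_periods(
    dust_series: Sequence[tuple[str, float]],
    heavy_threshold: float,
    low_threshold: float = 0.0,
) -> list[tuple[str, str]]:
    """Label sampling periods by mean dust concentration.

    >= heavy_threshold -> "heavy"; >= low_threshold -> "low"; else "none".
    Returns (period, label) pairs in input order.
    """
    if low_threshold > heavy_threshold:
        raise ValueError("low_threshold must not exceed heavy_threshold")
    out = []
    for period, conc in dust_series:
        if conc >= heavy_threshold:
            label = "heavy"
        elif conc >= low_threshold and low_threshold > 0:
            label = "low"
        else:
            label = "none"
        out.append((period, label))
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U test

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2.0)


def _exact_p(u_obs: float, n_a: int, n_b: int, alternative: str) -> float:
    """Exact p by enumerating all C(n_a + n_b, n_a) equally likely rank
    assignments (valid only without ties)."""
    n = n_a + n_b
    offset = n_a * (n_a + 1) / 2.0
    count_le = count_ge = total = 0
    for combo in itertools.combinations(range(1, n + 1), n_a):
        u = sum(combo) - offset
        total += 1
        if u <= u_obs + 1e-9:
            count_le += 1
        if u >= u_obs - 1e-9:
            count_ge += 1
    p_less = count_le / total
    p_greater = count_ge / total
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))


def _approx_p(u_obs: float, pooled: np.ndarray, n_a: int, n_b: int, alternative: str) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    sd = math.sqrt(var)
    if alternative == "greater":
        return float(stats.norm.sf((u_obs - mu - 0.5) / sd))
    if alternative == "less":
        return float(stats.norm.cdf((u_obs - mu + 0.5) / sd))
    z = (abs(u_obs - mu) - 0.5) / sd
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test of two independent samples.

    Returns (U, p) where U is the statistic of sample ``a`` (rank sum of a
    minus n_a(n_a+1)/2, midranks for ties). The p-value is exact — full
    enumeration of all C(n_a+n_b, n_a) labelings — when the pooled sample has
    at most 12 untied values, and otherwise uses the normal approximation
    with tie and continuity corrections. ``alternative`` is "two-sided"
    (2 x min one-sided, capped at 1), "less" (a shifted below b) or
    "greater". Identical pooled values give p = 1.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    u_obs = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        return u_obs, 1.0
    n_a, n_b = len(a), len(b)
    has_ties = len(np.unique(pooled)) < n_a + n_b
    if n_a + n_b <= EXACT_ENUMERATION_LIMIT and not has_ties:
        return u_obs, _exact_p(u_obs, n_a, n_b, alternative)
    return u_obs, _approx_p(u_obs, pooled, n_a, n_b, alternative)


# ---------------------------------------------------------------------------
# Dust-effect report

def _to_dataframe(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        df = samples.copy()
    else:
        df = pd.DataFrame(
            [{c: getattr(s, c) for c in FIELD_CSV_COLUMNS} for s in samples]
        )
    missing = set(FIELD_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"field data missing columns: {sorted(missing)}")
    return df


def dust_effect_report(
    samples: "pd.DataFrame | Iterable[FieldSample]",
    coarse_cutoff: float = COARSE_CUTOFF_UM,
    alternative: str = "two-sided",
) -> dict:
    """Test whether heavy-dust periods elevate the 1-NP/BkF ratio.

    Ratios with missing BkF are excluded (count logged and reported). Heavy
    periods are compared against the pooled non-/low-dust periods, on all
    size fractions and on coarse fractions only (lower bound >= cutoff).
    Returns a JSON-ready dict with per-fraction medians by group, group
    sizes, and the two Mann-Whitney (U, p) results.
    """
    df = _to_dataframe(samples)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(df["conc_bkf"] > 0, df["conc_1np"] / df["conc_bkf"], np.nan)
    df = df.assign(ratio=ratio)
    n_excluded = int(df["ratio"].isna().sum())
    if n_excluded:
        logger.info("excluding %d samples with missing/zero BkF", n_excluded)
    df = df.dropna(subset=["ratio"])
    df = df.assign(group=np.where(df["dust_label"] == "heavy", "heavy", "non_low"))

    def _test(sub: pd.DataFrame):
        heavy = sub.loc[sub["group"] == "heavy", "ratio"].to_numpy()
        other = sub.loc[sub["group"] == "non_low", "ratio"].to_numpy()
        if heavy.size == 0 or other.size == 0:
            return {"n_heavy": int(heavy.size), "n_non_low": int(other.size),
                    "U": None, "p": None}
        u, p = mann_whitney_u(heavy, other, alternative=alternative)
        return {"n_heavy": int(heavy.size), "n_non_low": int(other.size),
                "U": u, "p": p}

    coarse = df[df["fraction_lo_um"] >= coarse_cutoff]
    per_fraction = (
        df.groupby(["fraction_lo_um", "fraction_hi_um", "group"])["ratio"]
        .median()
        .unstack("group")
    )
    fractions = [
        {
            "fraction_lo_um": float(lo),
            "fraction_hi_um": float(hi),
            "median_ratio_heavy": (
                float(row["heavy"]) if "heavy" in row and pd.notna(row["heavy"]) else None
            ),
            "median_ratio_non_low": (
                float(row["non_low"]) if "non_low" in row and pd.notna(row["non_low"]) else None
            ),
        }
        for (lo, hi), row in per_fraction.iterrows()
    ]
    return {
        "coarse_cutoff_um": coarse_cutoff,
        "alternative": alternative,
        "n_excluded_missing_bkf": n_excluded,
        "fractions": fractions,
        "overall": _test(df),
        "coarse_only": _test(coarse),
    }


def format_dust_report(report: dict) -> str:
    """Human-readable text table for a dust-effect report."""
    lines = [
        "1-NP/BkF dust-effect report",
        f"  coarse cutoff: >= {report['coarse_cutoff_um']} um",
        f"  excluded (missing BkF): {report['n_excluded_missing_bkf']}",
        "",
        f"  {'fraction (um)':>16}  {'median heavy':>12}  {'median non/low':>14}",
    ]
    for fr in report["fractions"]:
        hi = fr["fraction_hi_um"]
        hi_s = f"{hi:g}" if math.isfinite(hi) else "inf"
        mh = fr["median_ratio_heavy"]
        mo = fr["median_ratio_non_low"]
        lines.append(
            f"  {fr['fraction_lo_um']:>7g}-{hi_s:<8} "
            f"{(f'{mh:.3f}' if mh is not None else 'n/a'):>12}  "
            f"{(f'{mo:.3f}' if mo is not None else 'n/a'):>14}"
        )
    for key, label in (("overall", "all fractions"), ("coarse_only", "coarse only")):
        t = report[key]
        if t["p"] is None:
            lines.append(f"  Mann-Whitney ({label}): insufficient data "
                         f"(n={t['n_heavy']}/{t['n_non_low']})")
        else:
            lines.append(
                f"  Mann-Whitney ({label}): U={t['U']:g}, p={t['p']:.4g} "
                f"(n_heavy={t['n_heavy']}, n_non_low={t['n_non_low']})"
            )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# CSV interface

def write_field_csv(samples: "pd.DataFrame | Iterable[FieldSample]", path) -> None:
    _to_dataframe(samples)[FIELD_CSV_COLUMNS].to_csv(
        path, index=False, float_format="%.17g"
    )


def read_field_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(FIELD_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"field CSV {path} missing columns: {sorted(missing)}")
    return df
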