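"""Bundled reference survey of pyrene + NO2 kinetics on mineral substrates.

Published flow-reactor measurements at 3 ppmv NO2, 298 K, in the dark:
pseudo-first-order rate constant k_obs (s^-1, +/- one standard error), the
apparent reaction probability gamma derived from it, percent pyrene degraded
(D_Py) and 1-nitropyrene yield (Y_1NP) after 2 h, a dinitropyrene formation
flag after 12 h, and the initial fractional pyrene surface coverage theta0.
Values are stored unscaled in SI units (the customary 1e5 / 1e8 / 1e2
presentation factors are applied only when formatting).

These rows serve as inputs for consistency checks of the collision-theory
conversion between k_obs and gamma; the package never fits to them.
"""

from __future__ import annotations

REFERENCE_CONDITIONS = {"no2_ppmv": 3.0, "temperature_k": 298.15, "pressure_pa": 101325.0}

#: name, k_obs (s^-1), k_obs_se, gamma, gamma_se, d_py (%), y_1np (%), dnp, theta0
REFERENCE_SUBSTRATES: list[dict] = [
    dict(name="Chinese desert dust (CDD)", k_obs=86e-5, k_obs_se=4e-5,
         gamma=14e-8, gamma_se=1e-8, d_py=96, y_1np=53, dnp="+", theta0=2.8e-2),
    dict(name="Arizona test dust (ATD)", k_obs=36e-5, k_obs_se=1e-5,
         gamma=6.1e-8, gamma_se=0.2e-8, d_py=88, y_1np=58, dnp="+", theta0=7.7e-2),
    dict(name="Kaolin", k_obs=110e-5, k_obs_se=10e-5,
         gamma=18e-8, gamma_se=1e-8, d_py=98, y_1np=60, dnp="+", theta0=1.5e-2),
    dict(name="Montmorillonite A", k_obs=53e-5, k_obs_se=5e-5,
         gamma=9.0e-8, gamma_se=0.8e-8, d_py=95, y_1np=89, dnp="+", theta0=2.0e-2),
    dict(name="Montmorillonite B", k_obs=29e-5, k_obs_se=4e-5,
         gamma=4.9e-8, gamma_se=0.7e-8, d_py=84, y_1np=79, dnp="+", theta0=5.8e-2),
    dict(name="Saponite", k_obs=39e-5, k_obs_se=3e-5,
         gamma=6.6e-8, gamma_se=0.4e-8, d_py=82, y_1np=73, dnp="-", theta0=0.27e-2),
    dict(name="Potassium feldspar", k_obs=1.1e-5, k_obs_se=0.2e-5,
         gamma=0.19e-8, gamma_se=0.03e-8, d_py=14, y_1np=10, dnp="-", theta0=11e-2),
    dict(name="Sodium feldspar", k_obs=0.30e-5, k_obs_se=0.06e-5,
         gamma=0.05e-8, gamma_se=0.01e-8, d_py=12, y_1np=6, dnp="-", theta0=58e-2),
    dict(name="Feldspar", k_obs=0.86e-5, k_obs_se=0.14e-5,
         gamma=0.15e-8, gamma_se=0.02e-8, d_py=17, y_1np=4, dnp="-", theta0=27e-2),
    dict(name="Limestone", k_obs=1.4e-5, k_obs_se=0.1e-5,
         gamma=0.24e-8, gamma_se=0.01e-8, d_py=18, y_1np=5, dnp="-", theta0=21e-2),
    dict(name="Dolomite", k_obs=0.83e-5, k_obs_se=0.15e-5,
         gamma=0.14e-8, gamma_se=0.03e-8, d_py=16, y_1np=4, dnp="-", theta0=11e-2),
    dict(name="Calcium sulfate", k_obs=1.5e-5, k_obs_se=0.5e-5,
         gamma=0.25e-8, gamma_se=0.09e-8, d_py=6, y_1np=0, dnp="-", theta0=49e-2),
    dict(name="Quartz", k_obs=1.7e-5, k_obs_se=0.1e-5,
         gamma=0.28e-8, gamma_se=0.01e-8, d_py=9, y_1np=5, dnp="-", theta0=63e-2),
    dict(name="Aluminum oxide", k_obs=0.25e-5, k_obs_se=0.0,
         gamma=0.04e-8, gamma_se=0.0, d_py=2, y_1np=1, dnp="-", theta0=6.7e-2),
    dict(name="Iron (III) oxide", k_obs=9.0e-5, k_obs_se=3.3e-5,
         gamma=1.5e-8, gamma_se=0.6e-8, d_py=17, y_1np=0, dnp="-", theta0=6.9e-2),
    dict(name="Titanium (IV) oxide", k_obs=1.4e-5, k_obs_se=0.0,
         gamma=0.24e-8, gamma_se=0.0, d_py=14, y_1np=3, dnp="-", theta0=5.2e-2),
    dict(name="Montmorillonite K10", k_obs=250e-5, k_obs_se=20e-5,
         gamma=43e-8, gamma_se=3e-8, d_py=100, y_1np=6, dnp="+", theta0=0.72e-2),
    dict(name="ATD w/ NH3 titration", k_obs=15e-5, k_obs_se=2e-5,
         gamma=2.5e-8, gamma_se=0.4e-8, d_py=62, y_1np=31, dnp="-", theta0=7.7e-2),
    dict(name="Graphite", k_obs=1.9e-5, k_obs_se=0.1e-5,
         gamma=0.32e-8, gamma_se=0.01e-8, d_py=9, y_1np=1, dnp="-", theta0=2.6e-2),
]

#: Ambient-extrapolation benchmark for Chinese desert dust: predicted k_obs at
#: 50 ppbv NO2 (s^-1) and the gamma derived from it.
AMBIENT_CDD = {"k_obs": 6.7e-5, "k_obs_se": 5.5e-5, "gamma": 7.3e-7, "gamma_se": 6.0e-7}
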