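"""Physical constants (CODATA 2018 / exact 2019-SI values) and package-wide defaults.

All internal quantities are SI: concentrations in molecules m^-3, rate
constants in s^-1, areas in m^2, molar masses in kg mol^-1. Mixing ratios
(ppmv/ppbv) appear only at I/O boundaries.
"""

#: Boltzmann constant, J K^-1 (exact by the 2019 SI redefinition).
K_B = 1.380649e-23

#: Molar gas constant, J mol^-1 K^-1 (exact: k_B * N_A).
R = 8.31446261815324

#: Avogadro constant, mol^-1 (exact).
N_A = 6.02214076e23

#: Molar mass of NO2, kg mol^-1.
M_NO2 = 0.0460055

#: Effective cross-section of a surface-adsorbed pyrene molecule, m^2
#: (~0.8 nm^2, the standard value for monolayer-coverage estimates).
SIGMA_PY = 0.8e-18

#: Default reactor temperature, K.
T_STD = 298.15

#: Default reactor pressure, Pa (1 atm).
P_STD = 101325.0

#: Default detection threshold for the dinitropyrene presence flag
#: (mole fraction of initial pyrene).
DNP_DETECTION_THRESHOLD = 0.005

#: Benchmark exposure time for degradation / yield summaries, s (2 h).
BENCHMARK_TIME_S = 7200.0

#: Benchmark exposure time for the dinitropyrene flag, s (12 h).
DNP_FLAG_TIME_S = 43200.0

#: Default lower bound defining "coarse" impactor fractions, um.
COARSE_CUTOFF_UM = 2.0

#: Default ambient NO2 mixing ratio for atmospheric extrapolation, ppbv.
AMBIENT_NO2_PPBV = 50.0

#: Default low-concentration reference for mechanism discrimination, ppbv.
MECHANISM_REF_PPBV = 100.0
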