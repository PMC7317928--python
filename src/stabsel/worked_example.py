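"""Published selection-gradient estimates used as a worked example.

These are the standardized gradients reported by a mating-trial study
of genital size and shape in the red flour beetle (Tribolium
castaneum): 498 pairs (216 successful, 282 failed spermatophore
transfers), five standardized traits per sex — centroid size (CS) and
the first four relative-warp shape scores (RW1-RW4).

The raw pair data were not deposited, but the printed gradient tables
are internally linked: eigendecomposing the nonlinear gradient matrix
reproduces the published canonical eigenvalues, and projecting beta
onto the published eigenvector rows reproduces the published theta
values. That linkage makes these tables a complete deterministic test
of the canonical-analysis machinery.

Matrices are stored exactly as printed (three decimals). The gamma
diagonals are the doubled quadratic gradients; off-diagonals are
correlational gradients.
"""

from __future__ import annotations

import numpy as np

TRAIT_NAMES = ["CS", "RW1", "RW2", "RW3", "RW4"]

N_PAIRS = 498
N_SUCCESS = 216
N_FAILURE = 282

# --- male (panel A) --------------------------------------------------------

MALE_BETA = np.array([0.030, 0.110, -0.043, 0.136, 0.110])

MALE_GAMMA = np.array([
    [-0.290, -0.061, -0.015, -0.065, -0.024],
    [-0.061, -0.018, -0.015, -0.052,  0.063],
    [-0.015, -0.015, -0.244,  0.093,  0.060],
    [-0.065, -0.052,  0.093,  0.100,  0.015],
    [-0.024,  0.063,  0.060,  0.015, -0.010],
])

MALE_R2_LINEAR = 0.030
MALE_R2_QUADRATIC = 0.106

# published canonical rotation of MALE_GAMMA (rows m1..m5)
MALE_M = np.array([
    [ 0.120,  0.229, -0.249, -0.927, -0.105],
    [ 0.172, -0.654, -0.123, -0.024, -0.726],
    [-0.190,  0.682, -0.136,  0.253, -0.645],
    [-0.024, -0.072, -0.951,  0.210,  0.214],
    [ 0.959,  0.222,  0.003,  0.176,  0.021],
])
MALE_LAMBDA = np.array([0.149, 0.063, -0.077, -0.279, -0.317])
MALE_THETA = np.array([-0.098, -0.144, 0.038, 0.084, 0.079])

# --- female (panel B) ------------------------------------------------------

FEMALE_BETA = np.array([-0.019, 0.037, 0.033, -0.110, -0.092])

FEMALE_GAMMA = np.array([
    [-0.236, -0.242, -0.137,  0.057,  0.015],
    [-0.242, -0.364, -0.137, -0.003, -0.052],
    [-0.137, -0.137,  0.082, -0.017, -0.045],
    [ 0.057, -0.003, -0.017, -0.044, -0.028],
    [ 0.015, -0.052, -0.045, -0.028, -0.140],
])

FEMALE_R2_LINEAR = 0.021
FEMALE_R2_QUADRATIC = 0.098

FEMALE_M = np.array([
    [ 0.299,  0.093, -0.929,  0.150,  0.128],
    [ 0.496, -0.430,  0.232,  0.718, -0.007],
    [ 0.418, -0.450,  0.071, -0.576,  0.535],
    [ 0.375, -0.191, -0.071, -0.359, -0.830],
    [-0.591, -0.753, -0.271,  0.043, -0.089],
])
FEMALE_LAMBDA = np.array([0.149, -0.009, -0.060, -0.175, -0.610])
FEMALE_THETA = np.array([-0.061, -0.096, -0.008, 0.099, -0.022])

# --- cross-sex interaction matrix (rows: female traits, cols: male traits)

INTERACTION = np.array([
    [ 0.062,  0.000,  0.000,  0.000,  0.000],
    [ 0.092,  0.016,  0.000,  0.000,  0.000],
    [-0.044, -0.029, -0.013,  0.000,  0.000],
    [ 0.036, -0.046, -0.031,  0.032,  0.000],
    [-0.025, -0.076,  0.007, -0.085,  0.031],
])
# the table prints the lower triangle of the female x male block; the
# two starred (significant) entries are (RW4_f, RW1_m) = -0.076 and
# (RW4_f, RW3_m) = -0.085
SIGNIFICANT_INTERACTIONS = [("RW4", "RW1", -0.076), ("RW4", "RW3", -0.085)]

# estimated fitness-peak coordinates on the two most stabilizing
# canonical axes (m4, m5) for each sex
MALE_PEAK_M4_M5 = np.array([0.222, 0.275])
FEMALE_PEAK_M4_M5 = np.array([0.202, -0.236])
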