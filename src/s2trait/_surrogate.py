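"""Coefficient tables for the analytic canopy-reflectance surrogate.

Version-tagged fixture constants, chosen by this package (not taken from any
radiative-transfer calibration).  Ten values per table, one per band, in
ascending band order (493, 560, 665, 704, 740, 783, 833, 865, 1610, 2190 nm).

The surrogate computes, per band b:

    k        = cos(ALIA)                        # extinction coefficient
    P0       = exp(-k * LAI)                    # gap fraction
    dm       = (Cm + CBC) * 1e4                 # dry-matter proxy
    rho_leaf = RHO_INF_b * exp(-(ALPHA_b*Cab + BETA_b*EWT + GAMMA_b*dm))
    R_b      = (1 - P0) * rho_leaf + P0 * soil * RHO_SOIL_b

Constraints the tables must obey (asserted by the test suite):
  * ALPHA > 0 at 493, 665, 704 nm (chlorophyll absorbs in blue/red) and
    exactly 0 in the SWIR (1610, 2190 nm);
  * BETA > 0 at 1610 and 2190 nm (water absorbs in the SWIR);
  * RHO_INF largest in the NIR plateau (783-865 nm);
  * RHO_SOIL increases from visible towards the SWIR (bright dry soil).
"""

import numpy as np

SURROGATE_VERSION = "1.0"

BAND_CENTERS_NM = np.array([493, 560, 665, 704, 740, 783, 833, 865, 1610, 2190])
BAND_NAMES = tuple(f"b{c}" for c in BAND_CENTERS_NM)
N_BANDS = 10

# Asymptotic leaf reflectance with no absorbers [dimensionless].
RHO_INF = np.array(
    [0.42, 0.48, 0.45, 0.50, 0.54, 0.56, 0.57, 0.57, 0.52, 0.46]
)

# Chlorophyll a+b specific absorption [cm^2 ug^-1].
ALPHA = np.array(
    [0.055, 0.030, 0.062, 0.028, 0.008, 0.002, 0.0, 0.0, 0.0, 0.0]
)

# Water specific absorption [cm^-1].
BETA = np.array(
    [0.0, 0.0, 0.0, 0.0, 0.5, 0.5, 1.0, 2.0, 38.0, 62.0]
)

# Dry-matter specific absorption against (Cm + CBC)*1e4 [dimensionless proxy].
GAMMA = np.array(
    [0.0002, 0.0002, 0.0002, 0.0002, 0.0003, 0.0003,
     0.0004, 0.0004, 0.0012, 0.0015]
)

# Reflectance of a maximally bright soil (scaled by the soil brightness
# parameter in [0, 1]).
RHO_SOIL = np.array(
    [0.07, 0.10, 0.14, 0.16, 0.18, 0.20, 0.21, 0.22, 0.30, 0.27]
)
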