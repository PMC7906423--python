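"""Frozen physical and operating constants used as package defaults.

Every default that the rest of the package relies on lives here, in SI
units unless the name says otherwise.  The configuration layer converts
clinical units (mmHg, ml/min, Fr) at the boundary only.
"""

# --- Blood rheology (Bird-Carreau shear-thinning fit for whole blood) ---
BLOOD_DENSITY = 1060.0          # kg/m^3
CARREAU_LAMBDA = 3.313          # s, time constant
CARREAU_N = 0.3568              # power-law index
CARREAU_MU0 = 0.056             # Pa s, low-shear plateau
CARREAU_MU_INF = 0.00345        # Pa s, high-shear plateau
NEWTONIAN_MU = 0.004            # Pa s, Newtonian comparator viscosity

LAMINAR_RE_THRESHOLD = 2300.0   # pipe-flow transition criterion

# --- Cardiac cycle timing ---
CYCLE_PERIOD = 0.8              # s
DIASTOLE = 0.5                  # s
SYSTOLE = 0.3                   # s
MEAN_RA_PRESSURE_MMHG = 3.0     # normal time/volume-averaged right-atrial pressure

# --- Chamber geometry (idealised right atrium) ---
SVC_DIAMETER = 0.01706          # m
IVC_DIAMETER = 0.01689          # m
TV_AREA = 9.95e-4               # m^2
RA_VOLUME_ML = 175.27           # target chamber volume, ml

# --- Catheter operating point ---
VENOUS_FLOW_ML_MIN = 400.0      # ml/min, venous-lumen return flow
VENOUS_GAUGE_MMHG = 248.0       # mmHg at the venous lumen
# Arterial-lumen gauge pressure [mmHg] and achieved flow [ml/min] per design.
ARTERIAL_GAUGE_MMHG = {"A": -250.0, "B": -250.0, "C": -250.0, "D": -188.0}
ARTERIAL_FLOW_ML_MIN = {"A": 350.0, "B": 380.0, "C": 360.0, "D": 370.0}

# --- Catheter dimensions: tip length [mm], outer diameter [Fr], lumen area [mm^2] ---
CATHETER_DIMENSIONS = {
    "A": {"tip_length_mm": 290.0, "outer_diameter_fr": 15.5, "lumen_area_mm2": 7.8},
    "B": {"tip_length_mm": 290.0, "outer_diameter_fr": 15.5, "lumen_area_mm2": 7.8},
    "C": {"tip_length_mm": 152.0, "outer_diameter_fr": 15.0, "lumen_area_mm2": 3.5},
    "D": {"tip_length_mm": 240.0, "outer_diameter_fr": 16.0, "lumen_area_mm2": 7.8},
}

# --- Tip sampling volumes: length x width x height [mm] per design ---
TIP_VOLUME_MM = {
    "A": (4.5, 25.0, 6.0),
    "B": (8.0, 10.0, 6.0),
    "C": (7.0, 7.0, 7.0),
    "D": (13.0, 9.0, 5.5),
}

# --- Solver settings ---
DT_SINGLE_PHASE = 0.005         # s
DT_MULTIPHASE = 0.001           # s
N_CYCLES = 4
RESIDUAL_TOLERANCE = 1e-4
ANALYSIS_CYCLE = 4              # 1-based index of the cycle used for results

# --- Convergence thresholds ---
MESH_WSS_ERROR_PCT = 0.5        # acceptable mesh-convergence error, average WSS
MESH_PROBE_ERROR_PCT = 3.0      # acceptable mesh-convergence error, probe velocity

# --- Shear-stress burden ---
PLATELET_TAU_THRESHOLD = 10.0   # Pa, platelet-activation surrogate threshold

# --- Unit conversions ---
MMHG_TO_PA = 133.322
ML_MIN_TO_M3_S = 1e-6 / 60.0
FR_TO_MM = 0.33

# --- Literature validation bands ---
VORTICITY_BAND = (37.0, 54.0)           # 1/s, in-vivo volume-averaged vorticity
VELOCITY_BAND = (0.174 - 0.027, 0.174 + 0.027)  # m/s, clinical mean +/- sd
PRESSURE_BAND_MMHG = (0.0, 5.0)         # mmHg, volume-averaged RA pressure
RECIRCULATION_SPEC_PCT = 1.0            # design requirement on Rf
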