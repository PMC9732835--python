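"""Published per-subject statistics used as inputs for recomputation.

These are the printed per-subject Pearson correlations from the 7T columnar
mapping study this package emulates (n = 7 subjects, values averaged across
hemispheres). They are inputs: the package's own statistics (Fisher z, paired
t) are run on them to reproduce the printed test statistics.
"""

from __future__ import annotations

import numpy as np

#: Radial vs surface-parallel correlations of the approach-vs-withdrawal map,
#: one row per subject: within-column (depth 0.1 vs 0.9), across columns in
#: deep layers, across columns in superficial layers.
AXIS_CORRELATIONS = {
    "r_within": np.array([0.71, 0.67, 0.68, 0.68, 0.74, 0.76, 0.57]),
    "r_across_deep": np.array([0.28, 0.26, 0.29, 0.25, 0.29, 0.24, 0.18]),
    "r_across_superficial": np.array([0.42, 0.33, 0.38, 0.34, 0.49, 0.27, 0.25]),
}

#: Printed paired-t statistics for the axis-correlation comparisons
#: (Fisher z then paired t): within vs across-deep, within vs
#: across-superficial.
AXIS_T_WITHIN_VS_DEEP = 16.82
AXIS_T_WITHIN_VS_SUPERFICIAL = 11.38

#: Gray-matter vs above-surface control correlations, one row per subject.
#: A: deep (1.92 mm) vs surface (0 mm), within gray matter.
#: B, C, D: deep vs planes 1.2, 1.92, and 2.4 mm above the cortical surface.
VESSEL_CONTROL_CORRELATIONS = {
    "A": np.array([0.82, 0.81, 0.80, 0.80, 0.82, 0.84, 0.73]),
    "B": np.array([0.19, 0.10, 0.15, 0.11, 0.22, 0.43, 0.10]),
    "C": np.array([0.12, 0.05, 0.09, 0.07, 0.15, 0.26, 0.07]),
    "D": np.array([0.12, 0.05, 0.09, 0.06, 0.14, 0.21, 0.07]),
}

#: Printed paired-t statistics on the raw correlations: A vs B, A vs C, A vs D.
VESSEL_T_A_VS_B = 16.53
VESSEL_T_A_VS_C = 31.22
VESSEL_T_A_VS_D = 41.0

#: Behavioral stop-distance summary (standard procedure, outside scanner).
SDP_MEAN_CM = 57.0
SDP_SD_CM = 11.3
#: Within-scanner virtual stop-distance summary.
SDP_SCANNER_MEAN_CM = 60.72
SDP_SCANNER_SD_CM = 15.01

#: Mean gray-matter thickness of the parietal ROI (mm).
MEAN_THICKNESS_MM = 2.37
#: Radial separation of the depth-0.1 and depth-0.9 sampling planes (mm).
RADIAL_SEPARATION_MM = 1.9
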