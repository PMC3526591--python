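"""Unit conversion constants.

All unit conversions in the package go through this table. Conventions:
lengths along the chamber axis in mm, trajectory coordinates in µm, time
in s for diffusion and min for tracking, diffusion coefficients in cm²/s
(the unit customary for small-molecule/protein diffusivities).
"""

CM_PER_MM = 0.1
MM_PER_CM = 10.0
MM2_PER_CM2 = 100.0
UM_PER_MM = 1000.0
MM_PER_UM = 1e-3
S_PER_MIN = 60.0
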