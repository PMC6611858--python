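"""Sample synthetic knees from the cohort statistics and simulate them.

Draws knees from the mean +/- SD geometry table (truncated normals with the
ordering constraints enforced hierarchically) and runs the native-knee
protocol at full extension on each, showing how anatomy spreads the
baseline contact and the relative pressure response.
"""

import numpy as np

import pfjsim as pj

rng = np.random.default_rng(2024)
spec = pj.ReconstructionSpec.from_technique("native")

print("knee  femur_width  patella_radius  baseline_peak  rel_peak_0deg")
for i in range(5):
    knee = pj.sample_knee(seed=rng)
    result = pj.run_case(knee, spec, angles=[0.0])
    print(f"{i:4d}  {knee.femur_width:11.1f}  {knee.patella_radius:14.1f}  "
          f"{result.baseline.peak():13.2f}  "
          f"{result.angle(0.0).peak_relative_mpa:13.3f}")
# baseline_peak is the stored contact pressure from the 0.5 mm approach
# (MPa); rel_peak is the additional pressure the native ligament adds at
# full extension.  Both vary with the sampled anatomy but stay the same
# order of magnitude across the cohort.
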