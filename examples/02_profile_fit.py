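"""Simulate, reconstruct and fit a longitudinal emission profile.

Runs the full chain on the homogeneous-PMMA reference setup (220 MeV/u
carbon, tracker at 90 degrees), fits the reconstructed profile with the
double-logistic model and extracts the range observables Delta40 and
delta40 whose position tracks the Bragg-peak depth.
"""

import numpy as np

from fragmon.detection import longitudinal_profile
from fragmon.pipeline import run_chain
from fragmon.profiles import fit_profile, range_observables
from fragmon.workflows import pmma_box_setup, profile_edges

beam, phantom, model, tracker = pmma_box_setup()
chain = run_chain(beam, phantom, model, tracker, n_tracks=20000, seed=12)
print(f"simulated 20000 fragments, detected {len(chain['detected'])}")

edges = profile_edges(beam, phantom, model)
profile = longitudinal_profile(chain["poca_points"], edges,
                               weights=chain["weights"],
                               axis=np.asarray(beam.direction))
params = fit_profile(profile)
obs = range_observables(params)

print(f"fall-off midpoint p1 = {params.p1:.2f} cm, width p2 = {params.p2:.2f} cm")
print(f"Delta40 = {obs.delta40:.2f} +/- {obs.err_delta40:.2f} cm")
print(f"delta40 = {obs.delta40_tangent:.2f} +/- {obs.err_delta40_tangent:.2f} cm")
print("Both observables ride on the distal fall-off: a shift of the Bragg "
      "peak shifts them one-to-one, which is what makes them range monitors.")
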