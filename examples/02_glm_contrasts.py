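"""First-level GLM on a synthetic run: contrast t maps and thresholding.

Fits HRF-convolved boxcar regressors (plus RT modulator, high-pass basis and
constant) to a simulated run and reports the colour-vs-semantic contrast in
the generator's occipital zones, then applies the voxel-p + cluster-extent
rule.
"""

import numpy as np

import gradconn as g

subject = g.simulate_subject(seed=7)
dm = g.build_design_matrix(subject.design, subject.acquisition, rt_s=subject.rt_s)
fit = g.fit_glm(subject.run, dm)
tmap = g.contrast_map(fit, {"colour": 1, "semantic": -1}, label="colour-semantic")

print(f"design columns: {dm.names}")
print(f"degrees of freedom: {fit.df}")
for zone, mask in subject.geometry.zones.items():
    print(f"mean t in {zone:8s} zone: {tmap.data[mask].mean():6.2f}")
mask, clusters = g.threshold_map(tmap, p_voxel=0.005, extent_mm3=270.0)
print(f"suprathreshold clusters (p<.005, >=270 mm^3): {len(clusters)}")
print(f"largest cluster: {clusters[0]['n_voxels']} voxels, peak t = {clusters[0]['peak_value']:.1f}")
print()
print("The concept zone carries the strongest colour>semantic effect, the")
print("percept zone the weakest - the injected spatial layout.")
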