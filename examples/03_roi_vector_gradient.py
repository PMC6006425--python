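"""Vectors-of-ROI gradient mapping along the two ventral strips.

Computes anchors from the strip masks, fits the piecewise-linear spline,
places 13 equidistant 3-mm spheres per strip, extracts per-subject contrast
profiles for a small cohort and runs the vector x position interaction ANOVA
with gated follow-ups.
"""

import numpy as np

import gradconn as g
from gradconn.volumes import Volume

geometry = g.default_geometry()
contrasts = {
    "colour-control": {"colour": 1, "control": -1},
    "semantic-control": {"semantic": 1, "control": -1},
    "colour-semantic": {"colour": 1, "semantic": -1},
}

vectors = {}
for strip in ("FG", "ITG"):
    anchors = g.compute_anchors(
        Volume(geometry.sectors[strip].astype(float), geometry.affine), 5, strip
    )
    vectors[strip] = g.place_rois(g.fit_spline(anchors), anchors, 2, 3.0, label=strip)
vectors["ITG"], _ = g.match_vectors(vectors["FG"], vectors["ITG"])
print(f"ROIs per vector: {len(vectors['FG'])} (radius 3 mm)")

maps = {c: [] for c in contrasts}
for s in range(8):
    subj = g.simulate_subject(seed=100 + s, geometry=geometry)
    dm = g.build_design_matrix(subj.design, subj.acquisition, rt_s=subj.rt_s)
    fit = g.fit_glm(subj.run, dm)
    for c, w in contrasts.items():
        maps[c].append(g.contrast_map(fit, w, kind="beta", label=c))

profiles = {
    v: {c: g.extract_profile(maps[c], vectors[v], c) for c in contrasts}
    for v in ("FG", "ITG")
}
prof = profiles["FG"]["colour-control"]
print("FG colour-vs-control profile (caudal -> rostral):")
print("  ", np.round(prof.mean, 2))

res = g.vector_interaction_test(profiles)
tw = res["three_way"]
print(
    f"contrast x vector x position: F({tw['df1']:.0f},{tw['df2']:.0f}) = "
    f"{tw['F']:.1f}, p = {tw['p']:.2g}, partial eta^2 = {tw['partial_eta_sq']:.2f}"
)
for c in contrasts:
    row = res["per_contrast"][c]
    n_sig = int(res["followups"][c]["significant"].sum()) if c in res["followups"] else 0
    print(f"  {c:17s}: vector x position p = {row['p']:.2g}; {n_sig} positions differ")
print()
print("Profiles rise caudal->rostral (perceptual to conceptual); the two")
print("strips evolve differently, hence the significant interactions.")
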