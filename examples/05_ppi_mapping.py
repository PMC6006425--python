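"""Psychophysiological interaction mapping with an IFG seed.

Extracts the seed sphere's BOLD, deconvolves it to neural space, builds the
colour-vs-semantic interaction regressor and maps voxels whose coupling with
the seed strengthens during colour pairing.
"""

import numpy as np

import gradconn as g

subject = g.simulate_subject(seed=42)
geometry = subject.geometry

seed = g.extract_seed(subject.run, geometry.node_coords["IFG"], radius_mm=6.0)
ppi = g.build_ppi_design(
    seed, subject.design, {"colour": 1, "semantic": -1}, subject.acquisition
)
result = g.ppi_map(subject.run, ppi, p_voxel=0.005, extent_mm3=270.0)

print(f"seed sphere at {tuple(map(float, geometry.node_coords['IFG']))} mm, radius 6 mm")
print(f"suprathreshold interaction clusters: {len(result.clusters)}")
for c in result.clusters:
    print(
        f"  {c['n_voxels']:3d} voxels ({c['volume_mm3']:.0f} mm^3), "
        f"peak t = {c['peak_value']:.1f} at ijk {c['peak_ijk']}"
    )
blob, _ = geometry.node_blob("OCC-C")
print(f"cluster overlaps the modulated occipital-concept node: {bool((result.mask & blob).any())}")
print()
print("The ground-truth network boosts the IFG -> occipital-concept")
print("connection during colour blocks; the PPI map recovers exactly that")
print("coupling change.")
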