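"""Top-down vs bottom-up network comparison with FFX/RFX Bayesian selection.

Generates node BOLD series from the top-down architecture for a small
cohort, fits both candidate architectures by nonlinear least squares, and
adjudicates them with fixed-effects posteriors and random-effects exceedance
probabilities.
"""

import numpy as np

import gradconn as g
from gradconn.design import AcquisitionSpec, build_main_task_design
from gradconn.model_selection import ffx_select, fit_bilinear, rfx_select
from gradconn.simulate import observe_nodes

design = build_main_task_design(blocks_per_condition=2, order_seed=0)
acq = AcquisitionSpec.for_design(design)
td, bu = g.top_down_model(), g.bottom_up_model()

z = g.simulate_network(td, design, dt=0.1)  # ground truth: top-down
lme = {"top-down": [], "bottom-up": []}
n_subjects = 6
for s in range(n_subjects):
    obs = observe_nodes(z, 0.1, acq, noise_sd=0.1, seed=900 + s)
    for name, template in (("top-down", td), ("bottom-up", bu)):
        fit = fit_bilinear(obs, design, template, acq, dt=0.2, n_starts=1, seed=s)
        lme[name].append(fit.log_evidence)
lme = {k: np.array(v) for k, v in lme.items()}

print(f"{n_subjects} subjects, per-subject log-evidence difference (td - bu):")
print("  ", np.round(lme["top-down"] - lme["bottom-up"], 1))
ffx = ffx_select(lme)
rfx = rfx_select(lme, n_samples=20_000, seed=0)
for i, name in enumerate(ffx.models):
    print(
        f"  {name:10s}: FFX posterior = {ffx.ffx_posterior[i]:.4f}, "
        f"RFX alpha = {rfx.alpha[i]:.2f}, exceedance = {rfx.exceedance[i]:.4f}"
    )
print()
print("Both selection schemes decisively favour the generating top-down")
print("architecture: the data carry the signature of where the task input")
print("enters and which connection the colour context modulates.")
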