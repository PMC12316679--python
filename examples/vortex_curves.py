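"""The vortex curve and the microvessel type indicator (MTI).

Plotting dR2*(t) against dR2(t) over the bolus first pass traces a loop
whenever the two vascular compartments see the bolus at different times.
A positive lag of the SE curve (the bolus reaches arterioles before
capillaries) gives a clockwise loop and a positive MTI; a negative lag
(capillaries fill before venules drive the GE signal) gives a
counter-clockwise loop and a negative MTI.
"""

from dataclasses import replace

import numpy as np

from vaimri import (
    delta_r2_series,
    estimate_baseline,
    find_bolus_peak,
    first_pass_window,
    generate_phantom,
)
from vaimri.metrics import mti_loop_area
from vaimri.phantom import DEFAULT_TISSUES, PhantomConfig

for tau in (+0.8, 0.0, -0.8):
    tissues = dict(DEFAULT_TISSUES)
    tissues["NAWM"] = replace(tissues["NAWM"], tau_se=tau)
    ds = generate_phantom(PhantomConfig(tissues=tissues))

    s0, valid = estimate_baseline(ds.ge)
    dr2s = delta_r2_series(ds.ge, s0, valid)
    s0s, valids = estimate_baseline(ds.se)
    dr2 = delta_r2_series(ds.se, s0s, valids)

    nawm = ds.roi_set["NAWM"]
    curve_ge = np.nanmean(dr2s[nawm], axis=0)
    curve_se = np.nanmean(dr2[nawm], axis=0)
    peak = find_bolus_peak(curve_ge, search_from=8)
    w = first_pass_window(peak, ds.ge.params.n_dynamics)

    mti = mti_loop_area(curve_se[w.slice], curve_ge[w.slice])
    kind = "arteriole-dominated" if mti > 0.2 else (
        "venule-dominated" if mti < -0.2 else "no dominance"
    )
    print(f"SE lag {tau:+.1f} s -> MTI = {mti:+7.3f}  ({kind})")

print(
    "\nMTI is the signed loop area in units of s^-2: its sign reports which "
    "vessel type dominates the voxel, its magnitude grows with the "
    "inter-compartment delay."
)
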