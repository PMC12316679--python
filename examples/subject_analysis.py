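"""Full single-subject analysis: from dynamic signals to microvascular maps.

Generates a noise-free phantom subject, runs the complete pipeline
(relaxometry -> AIF and rCBV with NAWM anchoring -> large-vessel
exclusion -> diffusion fit -> Q/VSI/MTI -> GE and SE CBF -> ROI
summaries) and compares recovered ROI means with the simulated truth.
"""

from vaimri import generate_phantom, run_subject_data
from vaimri.metrics import vessel_size_index

ds = generate_phantom()
res = run_subject_data(ds.ge, ds.se, ds.dwi, ds.bvals, ds.roi_set)

print(f"AIF scale factor (NAWM anchored to 3.2%): {res.aif_scale:.4f}")
print(
    f"first-pass window: dynamics {res.window.start}-{res.window.end} "
    f"around peak {res.window.peak_index}\n"
)

print(f"{'ROI':<6s}{'metric':<14s}{'recovered':>10s}{'truth':>10s}")
for roi in ("NAWM", "WMH", "DGM", "CGM"):
    tp = ds.config.tissues[roi]
    truth = {
        "Q": tp.q,
        "VSI": vessel_size_index(tp.d * 1e6, tp.rcbv, tp.q),
        "rCBV_percent": 100 * tp.rcbv,
        "D": tp.d * 1e6,
    }
    sub = res.summaries[res.summaries.roi == roi]
    for metric, tv in truth.items():
        got = float(sub[sub.metric == metric]["mean"].iloc[0])
        print(f"{roi:<6s}{metric:<14s}{got:>10.3f}{tv:>10.3f}")

print(
    "\nQ (s^-1/3) tracks microvessel density, VSI (um) the weighted mean "
    "vessel radius, rCBV (%) the blood volume fraction and D (um^2/s) the "
    "parenchymal diffusion coefficient; the lesion tissue shows the "
    "expected lower Q / higher VSI pattern."
)
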