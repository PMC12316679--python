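"""Generate a phantom subject and inspect its ground truth.

The phantom runs the vessel-architecture model forward: gamma-variate
bolus, exponential residue functions, the 2/3-power SE relaxation law and
mono-exponential diffusion decay, on a blocky anatomy with cortical and
deep gray matter, normal-appearing white matter, lesions, ventricles and
an arterial column.
"""

import numpy as np

from vaimri import generate_phantom
from vaimri.phantom import PhantomConfig

dataset = generate_phantom(PhantomConfig(seed=1))

print("label counts:")
for name, mask in dataset.roi_set.labels.items():
    print(f"  {name:<16s} {int(mask.sum()):5d} voxels")

print("\nper-tissue ground truth:")
print(f"  {'tissue':<12s} {'Q':>6s} {'rCBV':>7s} {'D mm2/s':>9s} {'MTT s':>6s} {'tau s':>6s}")
for name, tp in dataset.config.tissues.items():
    print(
        f"  {name:<12s} {tp.q:6.2f} {tp.rcbv:7.3f} {tp.d:9.1e} "
        f"{tp.mtt:6.1f} {tp.tau_se:6.1f}"
    )

peak_ge = np.nanmax(dataset.ge.data[dataset.roi_set["NAWM"]])
base_ge = dataset.ge.data[dataset.roi_set["NAWM"]][0, 0]
print(
    f"\nNAWM GE signal drops from {base_ge:.0f} at baseline to "
    f"{np.min(dataset.ge.data[dataset.roi_set['NAWM']]):.0f} at the bolus peak;"
)
print(
    "the dip encodes the susceptibility effect of the contrast first pass "
    "that the pipeline converts back into relaxation rates."
)
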