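"""Simulate one variable-TR series and fit the voxel-wise T1 map.

The saturation-recovery model S(TR) = S0 (1 - exp(-TR/T1)) is sampled
at seven TRs from 150 to 6000 ms with Rician noise at SNR 50, then fit
per voxel; only voxels with R² > 0.75 survive masking.
"""

import numpy as np

import qmristats as q

geometry = q.Geometry(matrix=(32, 32), n_slices=1)
spec = q.default_study_spec(geometry=geometry)
protocol = q.AcquisitionProtocol(geometry=geometry)
truth = q.make_study(spec, seed=2)[0]
series, _ = q.simulate_animal(truth, protocol, sigma=q.sigma_for_snr(spec.s0, 50), seed=3)

t1_map = q.fit_t1_map(series, protocol)
labels = spec.label_volume()

print(f"TRs (ms): {protocol.tr_list_ms}")
print(f"valid voxels: {t1_map.n_valid} of {t1_map.values.size} (R² > {t1_map.r2_threshold})")
for region, reg in spec.regions.items():
    mask = (labels == reg.label) & t1_map.valid_mask
    est, true = t1_map.values[mask].mean(), truth.t1_ms[labels == reg.label].mean()
    print(f"{region:13s} fitted T1 = {est:7.1f} ms   truth = {true:7.1f} ms")
# The fitted ROI means track the per-animal ground truth to within the
# noise floor; background voxels (no signal) fail the R² mask.
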