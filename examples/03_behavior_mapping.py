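"""Map scattered cell observations to a dense behavior surface with GPR.

Scattered (x, y, behavior) observations under-sample the array — cell-free
voids would otherwise read as false nulls.  A GP with an anisotropic
squared-exponential kernel (hyperparameters tuned by expected-improvement
Bayesian optimization of the marginal likelihood) predicts the behavior on
a dense grid, and the surface is collapsed through the size calibration
into a size-response curve.
"""

import numpy as np

from nanomap import mapping
from nanomap.optics import exponential_profile, fit_size_calibration
from nanomap.synth import ResponseModel, make_scene

profile = exponential_profile(0.2, 20.0, length_um=10000.0)
calibration = fit_size_calibration(profile)
model = ResponseModel("axonal_growth", peak_size_um=5.0, noise_sd=0.1)
scene = make_scene(profile, model, 10000.0, void_fraction=0.3, seed=3)

obs = mapping.ObservationSet(
    "axonal_growth",
    scene.cells.rename(columns={"value": "z"})[["x_um", "y_um", "z"]]
    .sample(400, random_state=0).reset_index(drop=True))
train, test = mapping.split_holdout(obs, test_fraction=0.10, seed=0)
print(f"{len(obs)} observations -> {len(train)} train / {len(test)} test")

hyper, trace = mapping.optimize_hyperparameters(train, n_iterations=20,
                                                seed=0)
print(f"EI search ({len(trace)} evaluations): length scales "
      f"({hyper.length_scale_x:.0f}, {hyper.length_scale_y:.0f}) um, "
      f"noise sd {np.sqrt(hyper.noise_variance):.3f}")

surface = mapping.fit_surface(train, hyper, trace)
rmse, r2 = mapping.holdout_error(surface, test)
print(f"hold-out RMSE = {rmse:.3f}, R^2 = {r2:.3f}")

grid = mapping.predict_grid(surface, obs.bounding_box,
                            total_points=250_000)
print(f"predicted grid: {grid.total_points} points "
      f"({grid.z_mean.shape[0]} x {grid.z_mean.shape[1]}), "
      f"fills the cell-free voids with finite predictions")

curve = mapping.marginalize_to_size_curve(grid, calibration, n_size_bins=8)
best = int(np.argmax(curve.mean))
print("size-response curve (um -> mean behavior):")
for s, m in zip(curve.size_bins_um, curve.mean):
    print(f"  {s:7.2f}  {m:.3f}")
print(f"peak in the bin around {curve.size_bins_um[best]:.2f} um "
      f"(ground truth peak: {model.peak_size_um} um)")
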