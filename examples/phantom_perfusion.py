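"""Recover semiquantitative perfusion parameters from a digital phantom.

Builds a small noiseless dynamic series (22 frames, 9.8 s apart), pulls
the synovial time-intensity curve out of the 4D volume, and compares
the five estimated perfusion parameters with the phantom's closed-form
truth. Exact agreement here is what licenses the same estimators on
noisy data.
"""

from synovaquant import PhantomConfig, extract_tic, generate_dce_phantom, perfusion_params

config = PhantomConfig(grid_shape=(16, 12, 6), noise_sd=0.0, seed=1)
signal, labels, truth = generate_dce_phantom(config)

tic = extract_tic(signal, labels, config.frame_times, roi_label=1)
est = perfusion_params(tic)
ref = truth.params["synovium"]

print("synovium compartment, noiseless series")
print(f"{'parameter':<10}{'estimate':>12}{'truth':>12}")
for name in ("wash_in", "wash_out", "ttp", "pe", "iauc"):
    print(f"{name:<10}{getattr(est, name):>12.4f}{getattr(ref, name):>12.4f}")
print()
print("wash-in/out are a.u./min, ttp seconds, pe dimensionless, iauc a.u.·min;")
print("estimates match the closed-form truth because the phantom's kinetics")
print("are piecewise linear and the series is noise-free.")
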