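"""Forward-simulate a small scan and condition it: low-pass, SVD, energy norm.

Shows how much of the recorded energy the band-noise subtraction removes and
that pulse-energy normalization flattens the shot-to-shot amplitude jitter.
"""

import numpy as np

import fanpat as fp

geom = fp.build_array()
# adjacent poses at the scanner's 1.8 degree step: the thin fan still
# illuminates the wire in each acquisition
plan = fp.AcquisitionPlan(n_angles=4, angular_step=1.8, n_samples=4400)
fan = fp.default_illuminator(geom)
milk = fp.derive_optics(0.0075, 15.0)

wire = ((6.7, -0.4, 6.7), (6.7, 0.4, 6.7), 0.05, 1.0)
noise = fp.NoiseModel(seed=1)
planes = fp.simulate_scan(
    fp.PhantomModel(wires=(wire,)), geom, fan, plan, milk,
    directivity=fp.DirectivityModel(), noise=noise,
)

print("pulse energies (jittered):", [round(p.pulse_energy, 3) for p in planes])
clean, report = fp.preprocess_planes(planes, order=5, cutoff=14.5e6, k=10)
print(f"SVD discarded rank {report.discarded_rank};"
      f" mean energy fraction removed {report.noise_fraction:.2f}")
print("pulse energies after normalization:", [round(p.pulse_energy, 3) for p in clean])
rms_before = [float(np.sqrt(np.mean(p.samples**2))) for p in planes]
rms_after = [float(np.sqrt(np.mean(p.samples**2))) for p in clean]
print("per-plane RMS before:", ["%.3e" % v for v in rms_before])
print("per-plane RMS after: ", ["%.3e" % v for v in rms_after])
# The removed fraction is dominated by the injected cross-channel bands; the
# surviving record carries the wire's arcs, now on a common energy scale.
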