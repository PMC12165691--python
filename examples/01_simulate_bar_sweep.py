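"""Simulate a bar-sweep mapping session for one synthetic electrode.

Builds the standard 8-sweep aperture sequence (224 steps, 196.4 s per run),
simulates voltage with a known broadband pRF and alpha-suppression pRF, and
prints what the raw data look like: the event grid and the blank-period
spectrum, whose peak should sit at the electrode's alpha frequency.
"""

import numpy as np

from alphaprf import GroundTruthElectrode, StimulusDesign, run_duration, simulate_experiment
from alphaprf.preprocess import epoch_recording
from alphaprf.spectral import welch_psd

design = StimulusDesign()
electrode = GroundTruthElectrode(
    bb_prf=(2.0, 1.0, 1.2, 0.002, 0.0),  # center (2,1) deg, sigma 1.2 deg
    alpha_prf=(2.0, 1.0, 2.4, 0.001, 0.0),
    alpha_peak=10.5,
)
rec = simulate_experiment(design, [electrode], n_runs=2, seed=42)

print(f"run duration: {run_duration(design):.1f} s "
      f"({design.n_steps} steps of {design.step_duration} s + 2 x {design.pre_post_blank} s blank)")
print(f"voltage array: {rec.voltage.shape} (runs x electrodes x samples at {rec.sample_rate:.0f} Hz)")
print(f"blank steps in the sequence: {rec.apertures.blank.sum()} of {len(rec.apertures)}")

epochs = epoch_recording(rec)
blank = epochs.metadata["blank"].to_numpy()
f, psd = welch_psd(epochs.stimulus_slice()[blank, 0], rec.sample_rate)
band = (f >= 5) & (f <= 20)
peak = f[band][np.argmax(psd.mean(axis=0)[band])]
print(f"blank-period spectrum peaks at {peak:.0f} Hz "
      f"(ground-truth alpha at {electrode.alpha_peak} Hz)")
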