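"""Synthesize a recording and run the preprocessing front end.

A two-block session is rendered into continuous 6-channel EEG (evoked
P1/N1/P3 responses, a 1.5x gain on the attended site, 10 uV pink noise,
occasional blinks on Fp1), then bandpass filtered (0.1-25 Hz), epoched,
baseline corrected and artifact rejected (50 uV scalp / 80 uV Fp1).
"""

from serpbci.erp import assign_clusters
from serpbci.preprocess import bandpass, baseline_correct, epoch, reject_artifacts
from serpbci.protocol import ProtocolConfig, generate_schedule
from serpbci.synth import SubjectModel, simulate_recording

schedule = generate_schedule(ProtocolConfig(n_blocks=2, seed=0))
subject = SubjectModel(attention_gain=1.5, noise_sd_uV=10.0, blink_rate_hz=0.2, seed=0)
recording = simulate_recording(schedule, subject)
print(f"recording: {recording.data.shape[0]} channels x {recording.n_samples} samples "
      f"({recording.n_samples / recording.rate_hz:.0f} s at {recording.rate_hz:.0f} Hz)")

epochs = reject_artifacts(baseline_correct(epoch(bandpass(recording))))
kept = len(epochs.kept)
print(f"epochs: {kept}/{len(epochs)} kept "
      f"({epochs.provenance['rejected_eeg']} EEG, {epochs.provenance['rejected_eog']} EOG rejections)")

print("cluster sizes:", assign_clusters(epochs).counts())

# Each kept epoch is one single-trial SEP; the four clusters split them by
# (attended site, stimulated site) for the averaging stage.
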