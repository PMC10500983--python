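"""Decompose a synthetic ground-truth EMG recording.

Synthesizes a 15-unit, 64-channel, ~30-s recording at 20-dB SNR (a
trapezoidal contraction to 50% MVC), decomposes it with the convolutive
blind-source-separation pipeline, and scores every accepted pulse train
against the known discharge times.
"""

from mugrid.decomposition import decompose
from mugrid.mu_metrics import match_to_ground_truth
from mugrid.synthesis import validation_recording

emg = validation_recording(seed=5)
print(
    f"recording: {emg.n_channels} channels, {emg.n_samples / emg.fs:.0f} s, "
    f"{int(emg.trains.active_units().sum())} active units, SNR {emg.snr_db:.0f} dB"
)

result = decompose(emg, mode="whole")
print(f"accepted pulse trains: {result.n_units}  (rejected: {result.rejected})")

scores = match_to_ground_truth(result.accepted, emg.trains)
print(scores.round(3).to_string(index=False))
print()
print("RoA (rate of agreement) is matched discharges over matched plus")
print("unmatched; 1.0 means the train reproduces its ground-truth unit's")
print("discharge times exactly.  PNR > 28 dB is the acceptance gate.")
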