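"""Simulate one auditory oddball session and inspect its structure.

The oddball is the study's 5-minute screening measurement: three runs of 20
five-tone sequences (four standards, one deviant each) at a 960 ms onset
asynchrony.  Deviants carry the participant's planted N1/P2/N2/P3/late
response; standards only the exogenous N1-P2 complex.
"""

import numpy as np

import p300apt as pa

profile = pa.make_participant(seed=42, aptitude=0.8)
recording = pa.simulate_oddball_session(profile, seed=7)

kinds = [e.kind for e in recording.events]
print(f"channels: {recording.data.shape[0]} "
      f"({recording.channel_roles.count('eeg')} EEG + "
      f"{recording.channel_roles.count('eog')} EOG)")
print(f"duration: {recording.n_samples / recording.sampling_rate:.0f} s")
print(f"tones: {len(kinds)} ({kinds.count('deviant')} deviants, "
      f"{kinds.count('standard')} standards)")
print(f"planted N2 amplitude: {profile.components['N2'].amplitude_uV:.2f} uV "
      f"at {profile.components['N2'].latency_ms:.0f} ms (aptitude {profile.aptitude})")

# Expected: 288 s of stimulation plus run padding, 300 tones with a 1:4
# deviant:standard ratio, and a deeper N2 than an average participant would
# show (|N2| grows with the latent BCI aptitude in this generator).
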