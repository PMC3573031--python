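"""Classify a visual P300 speller session and score its performance.

Leave-one-run-out cross-validation with SWLDA, the accuracy-vs-repetitions
curve, the interpolated repetitions-to-70% aptitude metric, and the
information transfer rate.
"""

import numpy as np

import p300apt as pa

profile = pa.make_participant(seed=42, aptitude=0.8, montage="sparse16")
# scaled-down session: 1 letter per run, 8 sequences, 250 Hz
timing = pa.TimingConfig(letters_per_run=1, sequences_per_letter=8,
                         sampling_rate_hz=250.0)
recording = pa.simulate_bci_session(profile, "visual", timing, seed=7)
epochs = pa.preprocess_recording(recording)

run_ids = np.array([e.run_index for e in epochs.events])
runs = [epochs.subset(run_ids == r) for r in range(6)]
trials = pa.cross_validate(runs, ma_width=12, decim=12)

curve = pa.accuracy_vs_repetitions(trials, max_reps=8)
reps70 = pa.reps_to_criterion(curve)
print("accuracy by repetitions:", np.round(curve.accuracy_percent, 1))
print(f"repetitions to 70%: {reps70:.2f}")

if reps70 < pa.NOT_REACHED:
    seconds, per_min = pa.selection_time(reps70, "visual", timing)
    itr = pa.pierce_itr(curve.accuracy_percent[-1] / 100.0, 25, per_min)
    print(f"selection time at criterion: {seconds:.1f} s "
          f"({per_min:.1f} selections/min)")
    print(f"ITR at 8 repetitions: {itr:.1f} bits/min")

# Accuracy should rise with the number of repetitions (scores are summed
# over sequences before the row/column arg-max); a high-aptitude profile
# reaches the 70% criterion within a few repetitions.
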