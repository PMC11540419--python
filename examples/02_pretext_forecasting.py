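"""Self-supervised pre-training: forecast the next 40 samples from 7000.

Slices an unlabelled recording into overlapping (7000-sample window,
40-sample continuation) pairs, trains the 1-D CNN forecaster, and compares
its validation RMSE against the repeat-last-value baseline. A forecaster
below that baseline has genuinely learned the subject's EDA dynamics — those
conv-layer features are what the stress regressor later reuses.
"""

import edassl as e

rec = e.simulate_subject(e.default_sim_config(subject_seed=0, n_segments=4))
scaled, _ = e.normalize_recording(rec)
pairs = e.make_pretext_pairs(scaled)
print(f"{len(pairs)} pretext pairs from a {rec.duration:.0f}s recording "
      f"(window 7000, horizon 40, stride 100)")

baseline = e.last_value_baseline_rmse(pairs)
print(f"repeat-last-value baseline RMSE: {baseline:.5f} (unit-scaled signal)")

model = e.build_pretext_model(seed=0)
history = e.pretrain(
    model, pairs,
    e.pretext_train_config(max_epochs=6, patience=5, target_metric=baseline),
)
for i, v in enumerate(history["val_rmse"], 1):
    print(f"epoch {i}: validation forecast RMSE {v:.5f}")

final = min(history["val_rmse"])
verdict = "beats" if final < baseline else "does not yet beat"
print(f"\nforecaster {verdict} the last-value baseline "
      f"({final:.5f} vs {baseline:.5f})")
e.save_checkpoint("sim0_pretext.npz", model.get_weights(),
                  {"kind": "pretext", "subject_id": rec.subject_id, "seed": 0})
print("checkpoint written to sim0_pretext.npz")
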