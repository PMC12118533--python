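"""Small end-to-end run: SSIM fidelity matrix and state classification.

Runs the complete pipeline on a reduced two-state dataset (3 epochs per
state) and prints the 4x4 measured/modeled PSD-SSIM matrix — block-diagonal
when the model reproduces each state's spectrum — and the accuracy/ROC-AUC
of logistic-regression state classification for all four train-test
combinations.  (The full-scale run lives in scripts/acceptance.py.)
"""

import numpy as np

from koopmodes import PipelineConfig, run_two_state_experiment, synthetic_inputs

cfg = PipelineConfig(
    duration=60.0,  # 3 epochs of 20 s per state
    n_perm=50,
    n_boot=200,
    folds=3,
    connectivity=False,
    seed=1,
)
status, resolved = synthetic_inputs(cfg)
result = run_two_state_experiment(status, resolved, cfg)

print("PSD SSIM matrix over conditions:")
print(" ", result.ssim_psd.labels)
print(np.round(result.ssim_psd.matrix, 3))
print("\nstate classification (accuracy, ROC-AUC):")
for combo, metrics in result.classification_psd.results.items():
    print(f"  {combo}: {metrics['accuracy']:.2f}, {metrics['roc_auc']:.2f}")
# Within-state SSIM near 1 and between-state SSIM well below 0.5, with
# perfect classification in every combination, mean the generative models
# reproduce each state's spectral fingerprint without blurring the states.
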