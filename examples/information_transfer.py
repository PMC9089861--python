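"""Burst-mediated information transfer (scaled-down demonstration).

The bursting reference cell receives a calibrated somatic OU background
current plus six spines driven by Poisson bursts (2 Hz burst rate) whose
within-burst rate varies.  For each condition the output spike train is
binarized at 4 ms and the context-tree-weighting estimator gives its
entropy, the entropy normalized to the Poisson maximum at the measured
rate, and the mutual information with the burst-onset sequence.  Durations
here are short so the script finishes in a few minutes; the pipeline default
(ExperimentConfig.info_duration) is longer for tighter estimates.
"""

from ca3burst.pipeline import ExperimentConfig, run_information_transfer_experiment

config = ExperimentConfig(
    cell_type="athorny",
    info_duration=40_000.0,        # ms per condition (demo scale)
    calibration_duration=15_000.0,
    intra_burst_rates=(100.0, 200.0),
    recalibrate_per_rate=False,
    master_seed=1,
)
df = run_information_transfer_experiment(config)
cols = ["intra_burst_rate_hz", "rate_hz", "isi_cv",
        "entropy_bits_per_s", "normalized_entropy", "mi_bits_per_s"]
print(df[cols].round(3).to_string(index=False))
print("\nhigher intra-burst rates pack the same presynaptic spikes into")
print("tighter volleys; the bursting cell signals them with multi-spike")
print("responses, raising the MI between burst onsets and output spikes")
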