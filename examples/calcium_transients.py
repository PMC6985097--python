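"""Decompose ATP-evoked Ca2+ transients and compare control vs antagonist.

Simulates two coverslips of ROI fluorescence recordings (300 s, 1 Hz,
stimulus at 20 s): an untreated culture and one whose purinoceptor-mediated
response is attenuated to 20% (the "stunted" response of an antagonist such
as suramin).  Each trace is normalized to F/F0, screened for a response, and
decomposed into latency, 10-90% rise time, peak amplitude, AUC and decay tau.
"""

from astroquant import (
    TraceSimSpec,
    extract_features_batch,
    generate_trace_set,
    summarize_response_rates,
)

features = []
for attenuation, name in ((1.0, "control"), (0.2, "suramin")):
    spec = TraceSimSpec(
        n_roi=10,
        latency_s=23.0,
        rise_duration_s=6.0,
        decay_tau_s=70.0,
        nonresponder_fraction=0.1,
        treatment_attenuation=attenuation,
        noise_sd=0.02,
        seed=21,
    )
    traces, truth = generate_trace_set(
        spec, group={"div": "28", "treatment": name}
    )
    features.extend(extract_features_batch(traces))

table = summarize_response_rates(features, by=("treatment",))
cols = [
    "treatment", "n_traces", "percent_nonresponsive",
    "latency_s_mean", "rise_time_s_mean", "decay_tau_s_mean",
    "auc_mean", "peak_amplitude_mean",
]
print(table[cols].round(2).to_string(index=False))
print()
print("True parameters: latency 23 s, RT 4.8 s, tau 70 s; the antagonist group")
print("keeps its kinetics but its peak amplitude and AUC drop ~5-fold.")
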