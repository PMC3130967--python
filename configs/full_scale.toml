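[simulation]
n_datasets = 20
n_channels = 63
samples_per_epoch = 256
n_trials = 500
jitter = [20.0, 40.0, 60.0]
mean_latencies = [64.0, 128.0, 192.0]
fwhm = 20.0
between_jitter = 20.0
location_stride = 2
seed = 1000

[analysis]
L = 20
n_components = [10, 20, 30, 40, 50]
algorithms = ["infomax", "fastica", "jade"]
seed = 2000
include_single_subject = false

[evaluation]
peak_window = 20
report = "ra_report.tsv"
results_dir = "results"
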