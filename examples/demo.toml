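# Synthetic end-to-end demo: design -> helicity -> plant -> strips ->
# decompose -> rotamer fractions.
seed = 0

[[stages]]
name = "design"
[stages.params]
n_units = 4

[[stages]]
name = "helicity"
[stages.params]
dg_side = -0.6

[[stages]]
name = "plant"
[stages.params]
n_frames = 100
[stages.params.mixture]
mt = 0.8
tp = 0.2

[[stages]]
name = "strips"
[stages.params]
noise_sd = 0.02
owners = [[13, "HE21"]]

[[stages]]
name = "decompose"
[stages.params]
n_trials = 50

[[stages]]
name = "gmm"
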