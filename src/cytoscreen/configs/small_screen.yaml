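# Bundled small synthetic screen: 3 donors x 2 treatments x 20 wells
# (2 batches of 10), two-tier barcoding, 4 PBMC-like subsets with a
# bimodal CD161 on CD8 T cells.  `simulation: builtin` selects the
# package's reference generator; seed and size are overridable here.
seed: 0
simulation:
  builtin: true
  n_events: 400
  n_wells: 20
options:
  diff_target: "CD161hi CD8 T"
  diff_reference: "CD161lo CD8 T"
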