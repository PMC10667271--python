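# Bundled demo: simulate the full two-tissue, six-state, triplicate design
# with the default planted modules, then run every stage.
simulate:
  seed: 7
seed: 7
top_k: 400
outdir: demo_out
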