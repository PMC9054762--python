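# Default tentative polyalanine / helix-propensity score table.
# Alanine carries the largest weight; methionine, leucine and glutamine are
# also helix-promoting and carry smaller positive weights. All other
# residues score zero and break stretches. Values are configuration, not
# fitted constants; tests never depend on them.
name: tentative-helix-propensity
version: "1.0"
scores:
  A: 0.5
  M: 0.3
  L: 0.3
  Q: 0.2
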