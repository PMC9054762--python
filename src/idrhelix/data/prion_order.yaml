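# Amino acids ordered most to least prion-promoting, used only to order
# composition-difference output. The ordering follows the enrichment of
# residues in experimentally defined yeast prion domains relative to the
# proteome background (the statistics underlying the PLAAC classifier);
# it is display configuration, not a computed quantity.
source: "prion-domain amino-acid enrichment (PLAAC background statistics)"
order: [N, Q, Y, G, S, M, P, F, A, H, T, R, D, V, I, L, K, E, C, W]
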