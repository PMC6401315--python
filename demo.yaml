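# Desk-scale demonstration: 48 lines, four flights, one planted QTL.
seed: 42
n_tem: 24
n_tst: 24
n_cols: 6
pixel_size: 6.0
n_bare_points: 250
n_snps: 1200
qtls:
- chrom: 2
  trait: PH_4
  effect: 30.0
h2:
  PH_4: 0.6
scan_groups:
- BOTH
k_pcs: 3
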