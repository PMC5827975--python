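# Default benchmark run: 5 synthetic families under the standard study
# conditions, snapshots 1994-2014 in steps of 2 years.
seed: 1
n_families: 5
outdir: sdpbench_out
mode: synthetic
benchmark:
  years: [1994, 1996, 1998, 2000, 2002, 2004, 2006, 2008, 2010, 2012, 2014]
  redundancy_identity: 0.95
  min_sequences: 15
  reference_year: 2014
  xdet_rho_min: 0.8
  et_score_max: 2.0
  teao_score_max: 0.3
  s3det_ari_min: 0.8
  conservation_gap_cap: 0.10
  seed: 1
synthetic: {}   # defaults: 4 subfamilies x 8 sequences, 200 columns,
                # 10 conserved + 10 SDP columns, 5 binding residues
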