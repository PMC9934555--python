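{
  "note": "Hand-enumerated expectations for toy_counts.tsv / toy_wt_counts.tsv (protein_length 100, depth 1e6, default thresholds). Anchors per replicate: synonymous phi median = 1 (A10=, G20=, L30=), nonsense phi median = 0.01 (K40*, R50*, S60*; T90* is within the terminal 14-residue window and excluded). F7L fails the 3-SD wild-type rule in nonselect (freq 2.5e-4 < control mean 3e-4). I9V is fully depleted and floored to one pseudo-read in select. H8Y replicates disagree (phi 0.6 vs 0.002), giving a regularized se of ~0.3575 > 0.3. E6K (freq 4e-5) and M12T (freq 8e-6) fall below the 0.005% nonselect-frequency cut; M12T alone (8 counts per million) also fails the 10-cpm well-measured bound.",
  "filter_counts": {
    "n_variants_in": 20,
    "n_wt_indistinguishable": 1,
    "n_low_freq": 0,
    "n_scored": 19,
    "n_select_floored": 1,
    "n_high_se": 1,
    "n_below_min_freq": 2,
    "n_pass_quality": 16,
    "n_well_measured": 19
  },
  "exact_scores": {
    "p.D5N": "log(10)/log(100) = 0.5",
    "p.K11R": 1.0,
    "p.A10=": 1.0,
    "p.K40*": 0.0,
    "p.W18C": "log(200)/log(100)",
    "p.I9V": "log(0.1)/log(100) = -0.5",
    "p.T90*": "log(50)/log(100)"
  }
}
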