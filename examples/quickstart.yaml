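# Quickstart: simulate a small drug library, run the full pipeline with a
# decision tree, and write metrics under haini_output/.
seed: 2
output_dir: haini_output
simulate:
  n_drugs: 60
  n_pairs: 500
  label_noise: 0.05
min_class_count: 10
select_k: 20
forest_trees: 25
algorithm: dt
grid:
  max_depth: [5, null]
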