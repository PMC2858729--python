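# Full Situation-2 simulation grid: 3 effect sizes x 6 sample sizes x 6
# questionnaire lengths = 108 scenarios (item parameters fixed at truth,
# epsilon = 0).  Run with:
#   pro-power grid --config situation2_grid.yaml --out situation2.csv
es_irt: [0.2, 0.5, 0.8]
n_per_group: [100, 200, 300, 400, 500, 800]
n_items: [5, 10, 15, 20, 50, 100]
epsilon: 0.0
situation: 2
n_replicates: 1000
alpha: 0.05
seed: 42
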