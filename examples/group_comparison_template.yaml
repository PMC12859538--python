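# Template for heterogeneous group-comparison simulation settings.
#
# Each entry under `scenarios` describes one setting for a Dunnett-style
# design: every endpoint gets an intercept (control-group log-odds) and one
# offset per non-control dose group.  Endpoints whose offsets are all zero
# form the null block automatically; the rest form the alternative block.
# The placeholder values below are illustrative - edit intercepts, effects,
# rho and N to express your own settings, then run e.g.
#
#   multibin simulate --config examples/group_comparison_template.yaml \
#       --n-sim 1000 --method bonferroni --method mmm --seed 1 --out results.csv
#
dose_levels: [0.0, 2.5, 5.0, 10.0]
alpha: 0.05
scenarios:
  - id: null-mixed-intercepts
    kind: group_comparison
    N: 100
    rho: 0.5
    # all-null: 10 endpoints, three with rarer events, no dose effects
    intercepts: [-1.1, -1.1, -1.1, -1.1, -1.1, -1.1, -1.1, -2.75, -2.75, -2.75]
    effects:
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
  - id: two-responsive-endpoints
    kind: group_comparison
    N: 200
    rho: 0.9
    intercepts: [-2.2, -2.2, -2.2, -2.2, -2.2, -2.2, -2.2, -2.2, -2.2, -2.2]
    effects:
      - [0.5, 1.0, 1.5]   # increasing effect with dose
      - [0.5, 1.0, 1.5]
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
      - [0.0, 0.0, 0.0]
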