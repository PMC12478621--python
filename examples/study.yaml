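# Desk-scale simulation study: two conditions, two trials each.
# Full design: L in {3,4} x m in {3,5} x rho in {0,0.5} x {simple,complex}.
conditions:
  - {L: 3, m: 3, rho: 0.0, structure: simple, N: 300}
  - {L: 3, m: 5, rho: 0.5, structure: complex, N: 300}
trials: 2
seed: 1
n_eta: 10
fit:
  nodes_per_dim: 4
  tol: 3.0e-4
  inner_max_iter: 1
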