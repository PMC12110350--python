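# Default configuration: model constants, network spec, mode scheme,
# stimulus, integrator.  Printed constants follow the epileptic
# excitatory/inhibitory population model; the astrocyte coupling constants
# (k_ca, ca_th, kappa, mu_glu, eta_h, lambda_a, c_net) are calibrated --
# see docs/methods.md for the calibration procedure.
model:
  tau_ex: 1.97       # excitatory time-scale
  tau_in: 3.0        # inhibitory time-scale
  h_ex: -0.5         # excitatory input
  h_in: -1.4         # inhibitory input
  c1: 1.0            # excitatory self-coupling
  c2: 15.0           # inhibitory -> excitatory weight
  c3: 6.1            # excitatory -> inhibitory weight
  cu: 6.0            # astrocyte -> neuron weight
  lambda_a: 165.0    # astrocyte feedback strength (calibrated)
  k_ca: 15.0         # firing-rate -> calcium slope (calibrated)
  ca_th: 9.0         # calcium threshold (calibrated)
  kappa: 0.5         # glutamate-recovery coupling (calibrated; mode 4 sets 1)
  mu_glu: 1.0        # glutamate time constant (calibrated)
  eta_h: 800.0       # recovery time constant (calibrated)
  eps: 1000.0        # sigmoid base
  c_net: 6.0         # network coupling coefficient (calibrated)
  dt: 0.05           # integration step
  t_total: 100.0     # run duration (dimensionless time units, nominal ms)
network:
  n_nodes: 50
  n0: 2
  p: 0.5
  seed: 42
modes:
  scheme: stimulation
stimulus:
  kind: none         # none | random | sine | square
  intensity: 0.0
  n_targets: 0
  period: 10.0
  duty: 0.5
  seed: 0
integrator:
  method: euler      # euler | rk4
init: random         # random | zeros
seed: 0
analysis:
  transient_frac: 0.1
  cv_source: order_parameter   # order_parameter | mean_ex
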