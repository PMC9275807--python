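# Reference configuration of the electromotor command network.
#
# The five synapse rows are the published R-GA values (the configuration
# fitted against inter-pulse-interval patterns recorded from freely
# behaving Gnathonemus petersii), with shared constants threshold = 0,
# E_syn = -80, T = 1.
#
# Nucleus parameters and input currents are re-derived for this package:
# they were tuned so that, together with the R-GA synapses, the network
# reproduces the published behavioural anchors (resting rhythm ~120 ms,
# scallop minimum ~40 ms, acceleration plateau ~85 ms, cessation pause
# ~500 ms).  They are not published values.

integration:
  dt: 0.1            # ms, shared Euler step for nuclei and receptors

nuclei:
  CN:  {a: 0.03,  b: 0.25, c: -65.0, d: 11.0, regime: "phasic spiking"}
  DP:  {a: 0.015, b: 0.2,  c: -65.0, d: 8.0,  regime: "tonic spiking"}
  PCN: {a: 0.003, b: 0.2,  c: -65.0, d: 25.0, regime: "spike frequency adaptation"}
  VPd: {a: 0.003, b: 0.0,  c: -65.0, d: 6.0,  regime: "low-threshold spiking"}

synapses:
  shared: {threshold: 0.0, E_syn: -80.0, T: 1.0}
  IS_DP:  {alpha: 0.539, beta: 5.297e-3, g_syn: -1.658e-1, t_max: 177.288}
  IS_PCN: {alpha: 5.948, beta: 1.295e-3, g_syn: -3.077e-1, t_max: 167.175}
  ES_DP:  {alpha: 5.982, beta: 1.200e-1, g_syn: 2.381e-1,  t_max: 9.51458}
  ES_PCN: {alpha: 5.027, beta: 2.186e-1, g_syn: 1.997e-1,  t_max: 84.4537}
  ES_CDP: {alpha: 4.433, beta: 1.371e-2, g_syn: 6.471e-1,  t_max: 428.988}

baseline:
  CN: 0.65
  DP: 5.0
  PCN: 0.0
  VPd: 4.0

protocols:
  # One step per stimulated nucleus: onset 500 ms, duration 400 ms.
  total_duration: 1500.0
  init_duration: [1000.0, 2000.0]
  onset: 500.0
  duration: 400.0
  amplitudes:
    acceleration: {DP: 2.0}
    scallop: {PCN: 10.0}
    rasp: {DP: 2.0, PCN: 10.0}
    cessation: {VPd: 8.0}

generator:
  # Synthetic-target anchors (ms) with +/-20% seeded jitter across
  # exemplars, laid out on the simulation-case time frame below.
  resting_ipi: 120.0
  acceleration_plateau: 85.0
  scallop_floor: 40.0
  cessation_pause: 500.0
  jitter: 0.2
  onset: 500.0
  step_duration: 400.0
  total_duration: 1500.0
  recovery: 240.0

ga:
  population_size: 100
  elite_fraction: 0.10
  crossover_prob: 0.9
  mutation_prob: 0.1
  mutation_scale: 0.1
  max_generations: 200
  stop_fitness_ratio: 3.0
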