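# Default model and ground configuration (1.80 m / 80 kg reference subject).
# Any field may be overridden in a user config passed to
# ReflexWalker.from_config().
subject:
  height: 1.80       # m
  mass: 80.0         # kg
simulation:
  dt: 0.0005         # s, fixed integrator step (0.1-0.5 ms supported)
ground:
  k_n: 120000.0      # N/m   normal contact stiffness (at 80 kg)
  d_n: 1.0           # s/m   normal contact damping factor
  k_t: 80000.0       # N/m   tangential (stiction) stiffness
  d_t: 600.0         # N s/m tangential damping
  mu: 0.9            # Coulomb friction coefficient
  load_threshold_bw: 0.03  # leg-load detection threshold, fraction of weight
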