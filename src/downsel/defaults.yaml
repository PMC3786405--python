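# Model constants and plasticity rates shared by every experiment.
# Voltages are in units of the weight ceiling w_max; probabilities are per
# 1 ms step and per noise synapse.
constants:
  w_max: 1.0            # weight bound; firing threshold is 2*w_max,
                        # feedback gate z_th is w_max/5
  dt_ms: 1.0
  fb_window: 2          # feedback membrane integration, steps
  noise_per_neuron: 3   # non-plastic noise synapses at w_max each
  group_size: 18

rates:
  alpha_ff: 0.1         # wake potentiation increment, feedforward
  alpha_fb: 0.05        # ... feedback (changes more slowly)
  beta_ff: 0.01         # sleep down-selection decrement, feedforward
  beta_fb: 0.005        # ... feedback
  w_ceil: 0.9           # ceiling potentiation saturates at
  fb_ceil: 0.9          # ceiling for feedback weights
  conf_ff: 0.2          # weighted drive for the FF side of a coincidence
  conf_fb: 0.1          # ... FB side
  fb_coincidence_window: 2
  sustain_steps: 2      # consecutive spikes defining a strong burst

sleep:
  up_ms: 500
  up_noise_p: 0.20      # up-state noise activation probability
  down_ms: 500
  down_noise_p: 0.05    # down-state
  onset_ms: 0           # optional high-noise volley at up-state onset
  onset_noise_p: 0.8
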