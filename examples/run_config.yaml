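# Full run configuration with the training-protocol defaults.
# Any key may be omitted; values here are what the package assumes.
train:
  epochs: 200        # N_T, total training iterations (epochs)
  snapshots: 50      # N, posterior sample size (last-N epoch weights)
  lr: 5.0e-4         # initial Adam learning rate
  weight_decay: 1.0e-10
  batch_size: 64
  seed: 0
scheduler:
  factor: 0.1        # learning-rate reduction on plateau
  patience: 10       # epochs without validation improvement before reducing
noise:
  enabled: true      # SGLD gradient noise; the dropout benchmark disables it
  track_lr: current  # noise std s_t follows the current (or "initial") lr
loss:
  lambda_gm: 1.0     # weight of the gradient-magnitude term
model:
  widths: [32, 64, 128]
  leaky_slope: 0.01
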