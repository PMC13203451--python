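# Single-class YOLO11-style pose network, 10 keypoints.
# Rows: [from, repeats, module, args]; channel args are pre-width-scaling.
# The layer graph and block hyper-parameters are recorded here so that the
# parameter-count and GFLOP figures of the complexity reporter are auditable
# layer by layer.

backbone:
  - [-1, 1, conv, [64, 3, 2]]        # 0  P1/2
  - [-1, 1, conv, [128, 3, 2]]       # 1  P2/4
  - [-1, 2, c3k2, [256, false, 0.25]]# 2
  - [-1, 1, conv, [256, 3, 2]]       # 3  P3/8
  - [-1, 2, c3k2, [512, false, 0.25]]# 4
  - [-1, 1, conv, [512, 3, 2]]       # 5  P4/16
  - [-1, 2, c3k2, [512, true]]       # 6
  - [-1, 1, conv, [1024, 3, 2]]      # 7  P5/32
  - [-1, 2, c3k2, [1024, true]]      # 8
  - [-1, 1, sppf, [1024, 5]]         # 9
  - [-1, 2, c2psa, [1024]]           # 10

head:
  - [-1, 1, upsample, []]            # 11
  - [[-1, 6], 1, concat, []]         # 12
  - [-1, 2, c3k2, [512, false]]      # 13
  - [-1, 1, upsample, []]            # 14
  - [[-1, 4], 1, concat, []]         # 15
  - [-1, 2, c3k2, [256, false]]      # 16  P3 out
  - [-1, 1, conv, [256, 3, 2]]       # 17
  - [[-1, 13], 1, concat, []]        # 18
  - [-1, 2, c3k2, [512, false]]      # 19  P4 out
  - [-1, 1, conv, [512, 3, 2]]       # 20
  - [[-1, 10], 1, concat, []]        # 21
  - [-1, 2, c3k2, [1024, true]]      # 22  P5 out
  - [[16, 19, 22], 1, pose_head, []] # 23

scales:
  # depth gain, width gain, max channels, reg_max, channel divisor, input size
  nano:      {depth: 0.50, width: 0.25,   max_channels: 1024, reg_max: 16, divisor: 8, input_size: 640}
  tiny-test: {depth: 0.50, width: 0.0625, max_channels: 1024, reg_max: 12, divisor: 2, input_size: 160}

# Attention insertion defaults (the final model's configuration; see the
# methods note for how the unstated hyper-parameters were fixed).
insertions:
  uib_layers: [2, 4, 6, 13, 16, 19]   # shallow/intermediate C3k2 stacks (P2-P4)
  uib_expand: 1.5
  se_reduction: 16
  se_branches: 2
  ta_kernel: 7
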