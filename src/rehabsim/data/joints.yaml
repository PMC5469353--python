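# Per-joint controller parameters for the four trained degrees of freedom.
# r_min / r_star are percentages of the subject's ROM amplitude; kd_* in
# Nms/deg; t_init in s. rom_min/rom_max are nominal device ranges (deg) used
# when no subject-specific ROM has been measured.
elbow:
  rom_min: 0.0
  rom_max: 90.0
  r_min: 0.0
  r_star: 0.5
  kd_init: 0.5
  dkd_max: 2.89
  t_init: 2.0
wrist_PS:
  rom_min: -80.0
  rom_max: 80.0
  r_min: 0.3
  r_star: 2.5
  kd_init: 0.5
  dkd_max: 1.0
  t_init: 2.0
wrist_FE:
  rom_min: -60.0
  rom_max: 60.0
  r_min: 0.06
  r_star: 10.0
  kd_init: 0.33
  dkd_max: 0.25
  t_init: 2.0
wrist_RUD:
  rom_min: -30.0
  rom_max: 30.0
  r_min: 0.06
  r_star: 10.0
  kd_init: 0.3
  dkd_max: 0.25
  t_init: 2.0
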