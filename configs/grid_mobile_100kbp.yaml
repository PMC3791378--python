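- name: mobile_nc0_lacI1
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 0
  k_assoc_nc: 1800.0
  n_cognate: 1
  k_assoc_cognate: 4.19
  crowding: 0.0
  duration: 3000.0
- name: mobile_nc0_lacI10
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 0
  k_assoc_nc: 1800.0
  n_cognate: 10
  k_assoc_cognate: 4.04
  crowding: 0.0
  duration: 3000.0
- name: mobile_nc0_lacI100
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 0
  k_assoc_nc: 1800.0
  n_cognate: 100
  k_assoc_cognate: 4.11
  crowding: 0.0
  duration: 3000.0
- name: mobile_nc0_lacI1000
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 0
  k_assoc_nc: 1800.0
  n_cognate: 1000
  k_assoc_cognate: 4.19
  crowding: 0.0
  duration: 3000.0
- name: mobile_nc10000_lacI1
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 216
  k_assoc_nc: 2000.0
  n_cognate: 1
  k_assoc_cognate: 4.58
  crowding: 0.09
  duration: 3000.0
- name: mobile_nc10000_lacI10
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 216
  k_assoc_nc: 2000.0
  n_cognate: 10
  k_assoc_cognate: 4.63
  crowding: 0.09
  duration: 3000.0
- name: mobile_nc10000_lacI100
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 216
  k_assoc_nc: 2000.0
  n_cognate: 100
  k_assoc_cognate: 4.67
  crowding: 0.09
  duration: 3000.0
- name: mobile_nc10000_lacI1000
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 216
  k_assoc_nc: 2000.0
  n_cognate: 1000
  k_assoc_cognate: 4.74
  crowding: 0.09
  duration: 3000.0
- name: mobile_nc30000_lacI1
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 647
  k_assoc_nc: 2571.0
  n_cognate: 1
  k_assoc_cognate: 6.11
  crowding: 0.26
  duration: 3000.0
- name: mobile_nc30000_lacI10
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 647
  k_assoc_nc: 2571.0
  n_cognate: 10
  k_assoc_cognate: 6.1
  crowding: 0.26
  duration: 3000.0
- name: mobile_nc30000_lacI100
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 647
  k_assoc_nc: 2571.0
  n_cognate: 100
  k_assoc_cognate: 6.19
  crowding: 0.26
  duration: 3000.0
- name: mobile_nc30000_lacI1000
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 647
  k_assoc_nc: 2571.0
  n_cognate: 1000
  k_assoc_cognate: 6.32
  crowding: 0.26
  duration: 3000.0
- name: mobile_nc50000_lacI1
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 1078
  k_assoc_nc: 3600.0
  n_cognate: 1
  k_assoc_cognate: 8.63
  crowding: 0.42
  duration: 3000.0
- name: mobile_nc50000_lacI10
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 1078
  k_assoc_nc: 3600.0
  n_cognate: 10
  k_assoc_cognate: 8.76
  crowding: 0.42
  duration: 3000.0
- name: mobile_nc50000_lacI100
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 1078
  k_assoc_nc: 3600.0
  n_cognate: 100
  k_assoc_cognate: 8.73
  crowding: 0.42
  duration: 3000.0
- name: mobile_nc50000_lacI1000
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 1078
  k_assoc_nc: 3600.0
  n_cognate: 1000
  k_assoc_cognate: 8.88
  crowding: 0.42
  duration: 3000.0
- name: mobile_nc70000_lacI1
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 1509
  k_assoc_nc: 6000.0
  n_cognate: 1
  k_assoc_cognate: 13.15
  crowding: 0.55
  duration: 3000.0
- name: mobile_nc70000_lacI10
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 1509
  k_assoc_nc: 6000.0
  n_cognate: 10
  k_assoc_cognate: 13.05
  crowding: 0.55
  duration: 3000.0
- name: mobile_nc70000_lacI100
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 1509
  k_assoc_nc: 6000.0
  n_cognate: 100
  k_assoc_cognate: 13.06
  crowding: 0.55
  duration: 3000.0
- name: mobile_nc70000_lacI1000
  obstacle_mode: mobile
  l_sub: 100000
  n_nc: 1509
  k_assoc_nc: 6000.0
  n_cognate: 1000
  k_assoc_cognate: 13.26
  crowding: 0.55
  duration: 3000.0
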