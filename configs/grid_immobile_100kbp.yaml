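- name: immobile_nc0_lacI1
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 0
  k_assoc_nc: 0.0
  n_cognate: 1
  k_assoc_cognate: 7.37
  crowding: 0.0
  duration: 3000.0
- name: immobile_nc0_lacI10
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 0
  k_assoc_nc: 0.0
  n_cognate: 10
  k_assoc_cognate: 7.37
  crowding: 0.0
  duration: 3000.0
- name: immobile_nc0_lacI100
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 0
  k_assoc_nc: 0.0
  n_cognate: 100
  k_assoc_cognate: 7.37
  crowding: 0.0
  duration: 3000.0
- name: immobile_nc0_lacI1000
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 0
  k_assoc_nc: 0.0
  n_cognate: 1000
  k_assoc_cognate: 7.37
  crowding: 0.0
  duration: 3000.0
- name: immobile_nc10000_lacI1
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 216
  k_assoc_nc: 0.0
  n_cognate: 1
  k_assoc_cognate: 7.37
  crowding: 0.099
  duration: 3000.0
- name: immobile_nc10000_lacI10
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 216
  k_assoc_nc: 0.0
  n_cognate: 10
  k_assoc_cognate: 7.37
  crowding: 0.099
  duration: 3000.0
- name: immobile_nc10000_lacI100
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 216
  k_assoc_nc: 0.0
  n_cognate: 100
  k_assoc_cognate: 7.37
  crowding: 0.099
  duration: 3000.0
- name: immobile_nc10000_lacI1000
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 216
  k_assoc_nc: 0.0
  n_cognate: 1000
  k_assoc_cognate: 7.37
  crowding: 0.099
  duration: 3000.0
- name: immobile_nc30000_lacI1
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 647
  k_assoc_nc: 0.0
  n_cognate: 1
  k_assoc_cognate: 7.37
  crowding: 0.298
  duration: 3000.0
- name: immobile_nc30000_lacI10
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 647
  k_assoc_nc: 0.0
  n_cognate: 10
  k_assoc_cognate: 7.37
  crowding: 0.298
  duration: 3000.0
- name: immobile_nc30000_lacI100
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 647
  k_assoc_nc: 0.0
  n_cognate: 100
  k_assoc_cognate: 7.37
  crowding: 0.298
  duration: 3000.0
- name: immobile_nc30000_lacI1000
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 647
  k_assoc_nc: 0.0
  n_cognate: 1000
  k_assoc_cognate: 7.37
  crowding: 0.298
  duration: 3000.0
- name: immobile_nc40000_lacI1
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 863
  k_assoc_nc: 0.0
  n_cognate: 1
  k_assoc_cognate: 7.37
  crowding: 0.397
  duration: 3000.0
- name: immobile_nc40000_lacI10
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 863
  k_assoc_nc: 0.0
  n_cognate: 10
  k_assoc_cognate: 7.37
  crowding: 0.397
  duration: 3000.0
- name: immobile_nc40000_lacI100
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 863
  k_assoc_nc: 0.0
  n_cognate: 100
  k_assoc_cognate: 7.37
  crowding: 0.397
  duration: 3000.0
- name: immobile_nc40000_lacI1000
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 863
  k_assoc_nc: 0.0
  n_cognate: 1000
  k_assoc_cognate: 7.37
  crowding: 0.397
  duration: 3000.0
- name: immobile_nc50000_lacI1
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 1078
  k_assoc_nc: 0.0
  n_cognate: 1
  k_assoc_cognate: 7.37
  crowding: 0.496
  duration: 3000.0
- name: immobile_nc50000_lacI10
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 1078
  k_assoc_nc: 0.0
  n_cognate: 10
  k_assoc_cognate: 7.37
  crowding: 0.496
  duration: 3000.0
- name: immobile_nc50000_lacI100
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 1078
  k_assoc_nc: 0.0
  n_cognate: 100
  k_assoc_cognate: 7.37
  crowding: 0.496
  duration: 3000.0
- name: immobile_nc50000_lacI1000
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 1078
  k_assoc_nc: 0.0
  n_cognate: 1000
  k_assoc_cognate: 7.37
  crowding: 0.496
  duration: 3000.0
- name: immobile_nc70000_lacI1
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 1509
  k_assoc_nc: 0.0
  n_cognate: 1
  k_assoc_cognate: 7.37
  crowding: 0.6940000000000001
  duration: 3000.0
- name: immobile_nc70000_lacI10
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 1509
  k_assoc_nc: 0.0
  n_cognate: 10
  k_assoc_cognate: 7.37
  crowding: 0.6940000000000001
  duration: 3000.0
- name: immobile_nc70000_lacI100
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 1509
  k_assoc_nc: 0.0
  n_cognate: 100
  k_assoc_cognate: 7.37
  crowding: 0.6940000000000001
  duration: 3000.0
- name: immobile_nc70000_lacI1000
  obstacle_mode: immobile
  l_sub: 100000
  n_nc: 1509
  k_assoc_nc: 0.0
  n_cognate: 1000
  k_assoc_cognate: 7.37
  crowding: 0.6940000000000001
  duration: 3000.0
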