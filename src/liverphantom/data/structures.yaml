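structures:
- name: liver
  id: 15
  category: I
  base_A: 95.0
  detail_B: 160.0
  kappa_si: 0.96
  kappa_ap: 0.9166666666666666
- name: gallbladder
  id: 16
  category: I
  base_A: 82.0
  detail_B: 160.0
  kappa_si: 0.96
  kappa_ap: 0.9166666666666666
- name: pancreas
  id: 17
  category: I
  base_A: 100.0
  detail_B: 112.0
  kappa_si: 0.8
  kappa_ap: 0.6
- name: spleen
  id: 18
  category: I
  base_A: 25.0
  detail_B: 170.0
  kappa_si: 0.85
  kappa_ap: 0.6
- name: stomach
  id: 19
  category: I
  base_A: 85.0
  detail_B: 140.0
  kappa_si: 0.8
  kappa_ap: 0.6
- name: kidneys
  id: 20
  category: I
  base_A: 90.0
  detail_B: 105.0
  kappa_si: 0.75
  kappa_ap: 0.55
- name: pericardium
  id: 21
  category: I
  base_A: 45.0
  detail_B: 150.0
  kappa_si: 0.7
  kappa_ap: 0.4
- name: myocardium
  id: 22
  category: I
  base_A: 65.0
  detail_B: 150.0
  kappa_si: 0.7
  kappa_ap: 0.4
- name: heart_blood
  id: 23
  category: I
  base_A: 110.0
  detail_B: 150.0
  kappa_si: 0.7
  kappa_ap: 0.4
- name: muscle
  id: 2
  category: II
  base_A: 40.0
  detail_B: 140.0
  kappa_si: 0.15
  kappa_ap: 0.3
- name: body
  id: 1
  category: II
  base_A: 30.0
  detail_B: 80.0
  kappa_si: 0.35
  kappa_ap: 0.3
- name: static_marrow
  id: 3
  category: II
  base_A: 30.0
  detail_B: 80.0
  kappa_si: 0.0
  kappa_ap: 0.0
- name: intestine_wall
  id: 4
  category: II
  base_A: 30.0
  detail_B: 85.0
  kappa_si: 0.55
  kappa_ap: 0.45
- name: lungs
  id: 5
  category: III
  base_A: 18.0
  detail_B: null
  kappa_si: 0.5
  kappa_ap: 0.4
- name: airway_tree
  id: 6
  category: III
  base_A: 235.0
  detail_B: null
  kappa_si: 0.45
  kappa_ap: 0.3
- name: intestine_air
  id: 7
  category: III
  base_A: 40.0
  detail_B: null
  kappa_si: 0.55
  kappa_ap: 0.45
- name: esophagus_wall
  id: 8
  category: III
  base_A: 136.0
  detail_B: null
  kappa_si: 0.4
  kappa_ap: 0.2
- name: air
  id: 0
  category: III
  base_A: 40.0
  detail_B: null
  kappa_si: 0.0
  kappa_ap: 0.0
- name: rib
  id: 9
  category: IV
  base_A: 32.0
  detail_B: null
  kappa_si: 0.0
  kappa_ap: 0.0
- name: spine
  id: 10
  category: IV
  base_A: 38.0
  detail_B: null
  kappa_si: 0.0
  kappa_ap: 0.0
- name: cord
  id: 11
  category: IV
  base_A: 195.0
  detail_B: null
  kappa_si: 0.0
  kappa_ap: 0.0
- name: cortical_bone
  id: 12
  category: IV
  base_A: 28.0
  detail_B: null
  kappa_si: 0.0
  kappa_ap: 0.0
- name: cartilage
  id: 13
  category: IV
  base_A: 140.0
  detail_B: null
  kappa_si: 0.0
  kappa_ap: 0.0
- name: mobile_marrow
  id: 14
  category: IV
  base_A: 135.0
  detail_B: null
  kappa_si: 0.0
  kappa_ap: 0.0
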