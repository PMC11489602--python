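n_patients: 529
seed: 0
cohort_label: young
variables:
- name: simple motor tics
  prevalence: 0.998109640831758
  degenerate: true
- name: simple vocal tics
  prevalence: 0.941398865784499
- name: complex motor tics
  prevalence: 0.5198487712665406
- name: complex vocal tics
  prevalence: 0.47448015122873344
- name: coprolalia
  prevalence: 0.21361058601134217
- name: copropraxia
  prevalence: 0.15122873345935728
- name: palilalia
  prevalence: 0.29678638941398866
- name: echolalia
  prevalence: 0.24574669187145556
- name: echopraxia
  prevalence: 0.166351606805293
- name: touching people
  prevalence: 0.2381852551984877
- name: touching objects
  prevalence: 0.3648393194706994
- name: obsessions
  prevalence: 0.19848771266540643
- name: compulsions
  prevalence: 0.5671077504725898
- name: anxiety
  prevalence: 0.28166351606805295
- name: depression
  prevalence: 0.07750472589792061
- name: substance use disorder
  prevalence: 0.005671077504725898
- name: premonitory urges
  prevalence: 0.5595463137996219
- name: tic suppression
  prevalence: 0.7391304347826086
- name: hyperactivity
  prevalence: 0.2892249527410208
- name: inattention
  prevalence: 0.444234404536862
- name: self-injurious behavior
  prevalence: 0.3383742911153119
- name: aggression toward others
  prevalence: 0.11153119092627599
- name: impulsivity
  prevalence: 0.5992438563327032
- name: sleep disorders
  prevalence: 0.22117202268431002
latent_corr:
- - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 1.0
  - 0.51
  - 0.44999999999999996
  - 0.42
  - 0.42
  - 0.42
  - 0.39
  - 0.3
  - 0.3
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.51
  - 1.0
  - 0.6375
  - 0.595
  - 0.595
  - 0.595
  - 0.5525
  - 0.425
  - 0.425
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.44999999999999996
  - 0.6375
  - 1.0
  - 0.5249999999999999
  - 0.5249999999999999
  - 0.5249999999999999
  - 0.48750000000000004
  - 0.375
  - 0.375
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.42
  - 0.595
  - 0.5249999999999999
  - 1.0
  - 0.48999999999999994
  - 0.48999999999999994
  - 0.45499999999999996
  - 0.35
  - 0.35
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.42
  - 0.595
  - 0.5249999999999999
  - 0.48999999999999994
  - 1.0
  - 0.48999999999999994
  - 0.45499999999999996
  - 0.35
  - 0.35
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.42
  - 0.595
  - 0.5249999999999999
  - 0.48999999999999994
  - 0.48999999999999994
  - 1.0
  - 0.45499999999999996
  - 0.35
  - 0.35
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.39
  - 0.5525
  - 0.48750000000000004
  - 0.45499999999999996
  - 0.45499999999999996
  - 0.45499999999999996
  - 1.0
  - 0.325
  - 0.325
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.3
  - 0.425
  - 0.375
  - 0.35
  - 0.35
  - 0.35
  - 0.325
  - 1.0
  - 0.25
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.3
  - 0.425
  - 0.375
  - 0.35
  - 0.35
  - 0.35
  - 0.325
  - 0.25
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.48999999999999994
  - 0.35
  - 0.35
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.315
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.48999999999999994
  - 1.0
  - 0.35
  - 0.35
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.315
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.35
  - 0.35
  - 1.0
  - 0.25
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.225
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.35
  - 0.35
  - 0.25
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.225
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.36
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.36
  - 1.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.6000000000000001
  - 0.0
  - 0.4
  - 0.5599999999999999
  - 0.36000000000000004
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.6000000000000001
  - 1.0
  - 0.0
  - 0.375
  - 0.5249999999999999
  - 0.3375
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.315
  - 0.315
  - 0.225
  - 0.225
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 1.0
  - 0.0
  - 0.0
  - 0.0
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.4
  - 0.375
  - 0.0
  - 1.0
  - 0.35
  - 0.225
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.5599999999999999
  - 0.5249999999999999
  - 0.0
  - 0.35
  - 1.0
  - 0.315
- - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.0
  - 0.36000000000000004
  - 0.3375
  - 0.0
  - 0.225
  - 0.315
  - 1.0
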