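# Simulator Sickness Questionnaire: 16 symptoms rated 0-3 (none..severe).
# Each subscale covers exactly 7 symptoms; some symptoms belong to two
# subscales (the instrument's overlap).  Weights apply to the raw subscale
# sums; the total multiplies the sum of the three RAW sums by the total
# weight.  Editable data asset: the mapping is data, not code.
weights:
  nausea: 9.54
  oculomotor: 7.58
  disorientation: 13.92
  total: 3.74
items:
  - {id: 1,  name: general_discomfort,      subscales: [nausea, oculomotor]}
  - {id: 2,  name: fatigue,                 subscales: [oculomotor]}
  - {id: 3,  name: headache,                subscales: [oculomotor]}
  - {id: 4,  name: eye_strain,              subscales: [oculomotor]}
  - {id: 5,  name: difficulty_focusing,     subscales: [oculomotor, disorientation]}
  - {id: 6,  name: increased_salivation,    subscales: [nausea]}
  - {id: 7,  name: sweating,                subscales: [nausea]}
  - {id: 8,  name: nausea,                  subscales: [nausea, disorientation]}
  - {id: 9,  name: difficulty_concentrating, subscales: [nausea, oculomotor]}
  - {id: 10, name: fullness_of_head,        subscales: [disorientation]}
  - {id: 11, name: blurred_vision,          subscales: [oculomotor, disorientation]}
  - {id: 12, name: dizziness_eyes_open,     subscales: [disorientation]}
  - {id: 13, name: dizziness_eyes_closed,   subscales: [disorientation]}
  - {id: 14, name: vertigo,                 subscales: [disorientation]}
  - {id: 15, name: stomach_awareness,       subscales: [nausea]}
  - {id: 16, name: burping,                 subscales: [nausea]}
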