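# igroup Presence Questionnaire: 14 items rated 1-5 here (five-point
# anchors; scale maximum 70, neutral reference 35).  One general-presence
# item plus three subscales that partition the remaining 13 items.
# Reverse-keyed items are inverted (rating -> min+max-rating) before any
# summing.  Editable data asset.
scale: {min: 1, max: 5}
items:
  - {id: 1,  code: G1,    category: general,     reverse: false}
  - {id: 2,  code: SP1,   category: spatial,     reverse: false}
  - {id: 3,  code: SP2,   category: spatial,     reverse: true}
  - {id: 4,  code: SP3,   category: spatial,     reverse: false}
  - {id: 5,  code: SP4,   category: spatial,     reverse: false}
  - {id: 6,  code: SP5,   category: spatial,     reverse: false}
  - {id: 7,  code: INV1,  category: involvement, reverse: false}
  - {id: 8,  code: INV2,  category: involvement, reverse: false}
  - {id: 9,  code: INV3,  category: involvement, reverse: true}
  - {id: 10, code: INV4,  category: involvement, reverse: false}
  - {id: 11, code: REAL1, category: realism,     reverse: true}
  - {id: 12, code: REAL2, category: realism,     reverse: false}
  - {id: 13, code: REAL3, category: realism,     reverse: false}
  - {id: 14, code: REAL4, category: realism,     reverse: false}
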