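"""Score the three VR human-factors instruments.

A mildly symptomatic simulator-sickness response, a moderately present iPQ
response, and a favorable usability rating.
"""
import posturo as po

# SSQ: slight general discomfort (item 1) and slight nausea (item 8)
ssq_resp = [0] * 16
ssq_resp[0] = 1   # general discomfort: nausea + oculomotor subscales
ssq_resp[7] = 1   # nausea symptom: nausea + disorientation subscales
s = po.score_ssq(ssq_resp)
print(f"SSQ  nausea {s.nausea:6.2f}  oculomotor {s.oculomotor:6.2f}  "
      f"disorientation {s.disorientation:6.2f}  total {s.total:6.2f}"
      f"  -> {po.classify_ssq(s.total)}")
print("     (shared symptoms count toward every subscale they belong to;")
print("      totals above 100 would flag active simulator sickness)")

# iPQ: agreeable presence ratings (4 of 5), reverse-keyed items at 2
ipq_resp = [4] * 14
for idx in (2, 8, 10):       # reverse-keyed items (0-based positions)
    ipq_resp[idx] = 2
i = po.score_ipq(ipq_resp)
print(f"iPQ  total {i.total:.0f}/70 (neutral reference "
      f"{po.ipq_neutral_reference():.0f})  general {i.general:.0f}  "
      f"spatial {i.spatial:.0f}/25  involvement {i.involvement:.0f}/20  "
      f"realism {i.realism:.0f}/20")

# SUS: favorable alternating-keyed answers
sus_resp = [4 if k % 2 == 1 else 2 for k in range(1, 11)]
print(f"SUS  {po.score_sus(sus_resp):.1f}/100 "
      "(Brooke composite; ~68 is the conventional 'average usability' mark)")
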