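# Goodman's published parent-report SDQ three-band cutpoints (4-17 years).
# For each subscale: [cut1, cut2] where scores <= cut1 are "normal",
# cut1 < score <= cut2 "borderline", and score > cut2 "abnormal".
# The prosocial subscale is expressed here on its reversed (antisocial)
# scale, where higher scores mean greater difficulty: the original bands
# (normal >= 6, borderline 5, abnormal <= 4 on prosocial) map to
# normal <= 4, borderline 5, abnormal >= 6 after reversal.
emotional: [3, 4]
conduct: [2, 3]
hyperactivity: [5, 6]
peer: [2, 3]
antisocial: [4, 5]
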