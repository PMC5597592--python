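; Illustrative 4-to-1 style atoms-to-beads mapping for a DOPC-like lipid
; (heavy atoms only, CHARMM-style names). Weights are equal within each
; bead and rescaled to sum to 1 on load. This file is an example of the
; mapping dialect, NOT an authoritative force-field mapping.

[atoms]
N C11 C12 C13 C14 C15
P O11 O12 O13 O14
C1 C2 C3 O21 O31 O22 O32 C21 C31
C22 C23 C24 C25 C26 C27 C28 C29
C210 C211 C212 C213 C214 C215 C216 C217 C218
C32 C33 C34 C35 C36 C37 C38 C39
C310 C311 C312 C313 C314 C315 C316 C317 C318

NC3: N C11 C12 C13 C14 C15
PO4: P O11 O12 O13 O14
GL1: C1 C2 O21 C21 O22
GL2: C3 O31 C31 O32
C1A: C22 C23 C24 C25
D2A: C26 C27 C28 C29 C210*0.5
C3A: C210*0.5 C211 C212 C213 C214
C4A: C215 C216 C217 C218
C1B: C32 C33 C34 C35
D2B: C36 C37 C38 C39 C310*0.5
C3B: C310*0.5 C311 C312 C313 C314
C4B: C315 C316 C317 C318
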