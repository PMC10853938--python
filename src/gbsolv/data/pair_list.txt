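# Element pairs retained for the Born pair-energy features, in feature order.
# 36 of the 45 unordered pairs of the nine feature elements; the nine
# dropped (F-F, F-Br, F-I, S-I, Cl-Cl, Cl-I, Br-Br, Br-I, I-I) are those
# scarcest in typical small-organic solute collections -- same-halogen and
# heavy-halogen combinations almost never co-occur in one solute.  Edit to
# change the layout; the reduced model dimension follows the active list.
H-H
H-C
H-N
H-O
H-F
H-S
H-Cl
H-Br
H-I
C-C
C-N
C-O
C-F
C-S
C-Cl
C-Br
C-I
N-N
N-O
N-F
N-S
N-Cl
N-Br
N-I
O-O
O-F
O-S
O-Cl
O-Br
O-I
F-S
F-Cl
S-S
S-Cl
S-Br
Cl-Br
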