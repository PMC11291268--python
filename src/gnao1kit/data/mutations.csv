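mutation,disorder,onset_class,activity
G40R,DEE17,early,inactive
G45E,DEE17,very_early,inactive
S47G,DEE17,late,active
Q52P,DEE17,early,inactive
Q52R,DEE17,early,inactive
D174G,DEE17,early,inactive
L199P,DEE17,very_early,active
G203R,DEE17,early,active
R209C,NEDIM,late,active
C215Y,NEDIM,very_late,active
A227V,DEE17,early,active
Y231C,DEE17,early,active
Q233P,NEDIM,very_late,active
E237K,NEDIM,late,active
E246K,NEDIM,late,active
N270H,DEE17,early,inactive
F275S,DEE17,very_early,inactive
I279N,DEE17,very_early,inactive
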