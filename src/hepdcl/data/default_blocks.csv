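id,kind,formula,n_sites
1,core-amine,C10H26N4,2
A,aldehyde,C7H6O2,1
B,aldehyde,C7H6O,1
C,aldehyde,C14H10O,1
D,aldehyde,C8H8O2,1
E,aldehyde,C11H8O2,1
F,aldehyde,C11H8O2,1
G,aldehyde,C11H8O2,1
H,aldehyde,C8H8O3,1
I,aldehyde,C15H10O,1
J,aldehyde,C7H6O2,1
K,aldehyde,C12H10O2,1
L,aldehyde,C11H8O,1
M,aldehyde,C8H6O2,2
N,aldehyde,C11H8O,1
O,aldehyde,C8H7BrO3,1
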