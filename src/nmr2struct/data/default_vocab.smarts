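# default-cno vocabulary: simple C/N/O fragments with at most 7 atoms.
# One SMARTS per line; bit order in fingerprints follows file order.
[CH4]
[CH3]
[CH2]
[CH]
[CH0;X4]
[CX3]
[CX2]
[OX2H]
[OX2H0]
[OX1]
[NX3;H2]
[NX3;H1]
[NX3;H0]
[NX2]
[NX1]
C=C
C#C
C=O
C=N
C#N
N=N
N=O
C-O
C-N
N-O
O-O
N-N
CC
CCC
CC(C)C
CCCC
CCO
CC=O
COC
CCN
CN(C)C
OCO
NCO
OCC=O
NCC=O
CC(C)=O
CC(N)=O
CC(O)=O
[CX3](=O)[OX2H1]
[CX3](=O)[OX2H0]
[CX3](=O)[NX3]
[CX3H1]=O
[CX3](=[OX1])[CX4]
OC=N
N=CO
C=CC=C
C=CC=O
C=CC#N
C#CC
CC#N
CN=O
C[N+](=O)[O-]
c
n
o
cc
ccc
cccc
ccccc
c1ccccc1
cn
cnc
co
ncn
c1ccncc1
c1ccco1
c1ccc[nH]1
[cH0]
c-C
c-O
c-N
cC=O
cC#N
[R]
[R;X4]
[r3]
[r4]
[r5]
[r6]
[r7]
C1CC1
C1CCC1
C1CCCC1
C1CCCCC1
C1CO1
C1CN1
C1CCO1
C1CCN1
C1CCOC1
C1CCNC1
C1CCOCC1
C1CCNCC1
O1CCOC1
[OX2r5]
[OX2r6]
[NX3r5]
[NX3r6]
C=C1CCCC1
OC1CCCC1
[CX4](O)(O)
[CX4](N)(N)
N#CC#N
O=CC=O
CC(C)(C)C
CC(C)O
CC(C)N
CC(C)C=O
CCOC
CCOCC
CCNC
CCNCC
COC=O
CNC=O
OCCO
NCCN
OCCN
C=CO
C=CN
C=C(C)C
CC=CC
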