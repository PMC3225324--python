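code,name,smiles
A,alanine,[*:1]NC(C)C(=O)[*:2]
R,arginine,[*:1]NC(CCCNC(N)=N)C(=O)[*:2]
N,asparagine,[*:1]NC(CC(N)=O)C(=O)[*:2]
D,aspartate,[*:1]NC(CC(O)=O)C(=O)[*:2]
C,cysteine,[*:1]NC(CS)C(=O)[*:2]
E,glutamate,[*:1]NC(CCC(O)=O)C(=O)[*:2]
Q,glutamine,[*:1]NC(CCC(N)=O)C(=O)[*:2]
G,glycine,[*:1]NCC(=O)[*:2]
H,histidine,[*:1]NC(Cc1cnc[nH]1)C(=O)[*:2]
I,isoleucine,[*:1]NC(C(C)CC)C(=O)[*:2]
L,leucine,[*:1]NC(CC(C)C)C(=O)[*:2]
K,lysine,[*:1]NC(CCCCN)C(=O)[*:2]
M,methionine,[*:1]NC(CCSC)C(=O)[*:2]
F,phenylalanine,[*:1]NC(Cc1ccccc1)C(=O)[*:2]
P,proline,[*:1]N1CCCC1C(=O)[*:2]
S,serine,[*:1]NC(CO)C(=O)[*:2]
T,threonine,[*:1]NC(C(C)O)C(=O)[*:2]
W,tryptophan,[*:1]NC(Cc1c[nH]c2ccccc12)C(=O)[*:2]
Y,tyrosine,[*:1]NC(Cc1ccc(O)cc1)C(=O)[*:2]
V,valine,[*:1]NC(C(C)C)C(=O)[*:2]
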