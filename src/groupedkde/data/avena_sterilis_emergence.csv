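chtt_10mm,chtt_20mm,chtt_50mm,cylinder_1,cylinder_2,cylinder_3,cylinder_4
100,92,67,0,0,0,0
160,146,105,0,0,0,0
218,199,143,2,6,8,3
218,217,155,1,0,0,1
218,217,185,2,1,1,3
218,217,199,2,1,1,0
218,217,204,1,1,0,0
218,217,204,0,0,0,0
218,217,204,0,0,0,0
218,217,204,0,2,0,0
218,217,204,2,2,9,2
218,217,204,3,7,18,11
218,217,204,12,7,19,22
218,217,204,6,5,8,13
265,261,232,2,5,7,7
352,340,287,13,12,5,8
405,421,343,7,12,13,4
459,505,421,0,0,1,0
509,571,538,0,0,0,0
509,571,538,0,0,0,0
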