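,D1,D2,D3,D4,D5,D6,D7,D8,D9,D10
KNN,0.639,0.6575,0.5823,0.606,0.623,0.5147,0.6015,0.639,0.6837,0.713
NB,0.5682,0.6309,0.5964,0.6409,0.5473,0.4209,0.5909,0.6145,0.6739,0.7048
SVM,0.9729,0.9429,0.9243,0.9647,0.6029,0.5829,0.84,0.8629,0.899,0.9162
C4.5,0.8336,0.8373,0.7427,0.6927,0.6727,0.6891,0.7127,0.6455,0.8133,0.7818
TSK-FS,0.8343,0.8368,0.9543,0.9171,0.5943,0.5786,0.9071,0.9171,0.8805,0.8967
STL,0.8871,0.9014,0.8997,0.9167,0.8014,0.7335,0.9046,0.9217,0.9049,0.9123
LMPROJ,0.8828,0.8771,0.9157,0.9529,0.6314,0.6134,0.9171,0.9083,0.9129,0.9076
TSK-TL,0.98,0.9857,0.9976,0.9986,0.8583,0.8371,0.9786,0.9657,0.9857,0.9771
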