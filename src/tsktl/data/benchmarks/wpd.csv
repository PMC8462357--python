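,D1,D2,D3,D4,D5,D6,D7,D8,D9,D10
KNN,0.8771,0.8857,0.9623,0.9819,0.7529,0.7286,0.9157,0.8914,0.9143,0.9057
NB,0.5636,0.6127,0.8373,0.8345,0.2655,0.3164,0.7927,0.8309,0.7152,0.7382
SVM,0.9086,0.93,0.9571,0.96,0.59,0.5943,0.7914,0.7843,0.7439,0.7305
C4.5,0.8845,0.8818,0.9645,0.9655,0.7936,0.7745,0.7727,0.8136,0.8994,0.9006
TSK-FS,0.9157,0.9329,0.9614,0.9586,0.7271,0.7571,0.9043,0.8986,0.9217,0.9189
STL,0.8529,0.8843,0.9789,0.9717,0.8629,0.8457,0.9171,0.9297,0.9367,0.9133
LMPROJ,0.9286,0.9357,0.9773,0.9835,0.6829,0.6,0.89,0.8757,0.9286,0.919
TSK-TL,0.9586,0.9571,0.9971,0.9957,0.9543,0.9329,0.9614,0.9571,0.9714,0.9657
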