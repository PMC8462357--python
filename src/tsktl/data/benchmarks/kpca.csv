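,D1,D2,D3,D4,D5,D6,D7,D8,D9,D10
KNN,0.8813,0.905,0.9295,0.945,0.7034,0.7045,0.8827,0.8945,0.9063,0.9533
NB,0.776,0.894,0.912,0.926,0.556,0.6137,0.8109,0.8064,0.7358,0.7655
SVM,0.8167,0.9067,0.85,0.8367,0.6067,0.6833,0.87,0.8467,0.6689,0.6667
C4.5,0.8955,0.9789,0.8382,0.9591,0.5945,0.77,0.9218,0.7682,0.8345,0.981
TSK-FS,0.87,0.9557,0.936,0.968,0.724,0.738,0.8943,0.878,0.8687,0.952
STL,0.8414,0.9214,0.92,0.9343,0.8217,0.87,0.9186,0.8471,0.8771,0.921
LMPROJ,0.7781,0.894,0.812,0.8127,0.702,0.7423,0.8343,0.8,0.8667,0.9371
TSK-TL,0.912,0.982,0.95,0.982,0.8289,0.8743,0.942,0.92,0.928,0.9827
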