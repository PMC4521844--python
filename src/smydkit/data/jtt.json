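{"name":"JTT","order":"ARNDCQEGHILKMFPSTWYV","exchangeabilities_lower_triangle":[58,54,81,56,57,105,179,27,36,30,35,54,15,194,378,475,9,11,298,45,16,113,310,29,137,328,22,38,646,44,5,74,101,64,126,20,17,528,34,86,58,81,391,47,12,263,30,10,15,503,232,8,70,16,10,49,767,130,112,11,7,26,15,4,15,59,38,4,46,31,9,5,59,69,17,23,7,31,78,14,223,42,115,209,62,323,26,597,9,72,292,43,4,164,53,51,18,24,20,119,26,12,9,181,18,5,18,30,32,10,7,45,23,6,6,27,14,5,24,201,33,55,8,47,16,56,45,33,40,115,73,46,8,573,11,229,21,479,89,10,40,245,9,32,961,14,388,248,102,59,25,52,24,180,65,4,21,47,103,10,8,14,43,16,29,226,24,18,323,17,92,12,53,536,62,285,118,6,10,23,477,35,63,38,12,21,112,71,25,16],"frequencies":[0.076747923252,0.051690948309,0.042644957355,0.051543948456,0.019802980197,0.040751959248,0.06182993817,0.073151926848,0.022943977056,0.053760946239,0.091903908096,0.058675941324,0.023825976174,0.040125959874,0.050900949099,0.068764931235,0.058564941435,0.014260985739,0.032101967898,0.066004933995]}
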