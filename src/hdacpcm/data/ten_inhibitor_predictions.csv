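compound_id,label,HDAC2,HDAC8,HDAC4,HDAC7,HDAC6
TSA,pan,-0.720,0.342,1.027,0.660,0.087
SAHA,pan,-0.464,-1.092,0.687,1.031,-0.094
LBH589,pan,0.742,0.391,0.524,0.347,0.996
PXD-101,pan,0.327,-0.330,1.183,0.643,1.339
MGCD0103,class_I,0.296,-0.946,-0.557,-1.018,-0.963
FK228,class_I,0.954,-0.095,0.687,0.438,-0.167
Apicidin,class_I,0.238,0.096,-0.501,-0.176,-0.120
APHA,class_II,-0.196,-0.089,-0.204,-0.194,0.271
Tubacin,class_II,0.148,-0.687,-0.293,-0.301,1.414
NCT-10a,class_II,-0.405,-0.731,0.137,0.159,0.010
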