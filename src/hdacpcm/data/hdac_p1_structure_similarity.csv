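target_id,HDAC2,HDAC8,HDAC4,HDAC7,HDAC6
HDAC2,1.000,0.407,0.182,0.182,0.031
HDAC8,0.407,1.000,0.180,0.186,0.048
HDAC4,0.182,0.180,1.000,0.706,0.027
HDAC7,0.182,0.186,0.706,1.000,0.036
HDAC6,0.031,0.048,0.027,0.036,1.000
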