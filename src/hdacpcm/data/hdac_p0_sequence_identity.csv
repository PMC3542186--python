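target_id,HDAC1,HDAC2,HDAC3,HDAC8,HDAC4,HDAC5,HDAC7,HDAC9,HDAC6,HDAC10,HDAC11
HDAC2,85.1,100.0,51.9,30.7,10.2,9.6,9.7,9.9,9.4,14.2,18.9
HDAC8,30.8,30.7,34.4,100.0,9.0,8.4,9.9,10.8,8.1,13.6,21.4
HDAC4,11.1,10.2,9.5,9.0,100.0,58.4,46.9,54.3,20.6,11.1,8.6
HDAC7,10.0,9.7,10.5,9.9,46.9,40.5,100.0,39.7,19.1,13.0,9.6
HDAC6,9.5,9.4,7.7,8.1,20.6,17.2,19.1,16.6,100.0,23.4,7.4
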