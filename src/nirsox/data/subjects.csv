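subject,group,age,sex,height_cm,weight_kg
P1,POTS,14,F,175.7,58
P2,POTS,13,F,157.5,41.1
P3,POTS,16,F,168,63
P4,POTS,15,F,159.9,75.3
P5,POTS,11,M,149.9,44
P6,POTS,16,F,167,51.6
C1,control,22,M,170.6,64
C2,control,21,M,173,65
C3,control,18,F,145.3,51
C4,control,22,F,158.9,60
C5,control,21,F,155.4,55
C6,control,23,M,182.8,63
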