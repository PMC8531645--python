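animal,depth_mm,velocity_mps,damage
I,11.2,2.1,1
II,8.9,2.2,0
III,9.1,1.8,1
IV,10.8,1.8,1
V,10.8,1.8,1
VI,12.6,1.7,1
VII,8.9,2.2,1
VIII,6.9,2.2,1
IX,5.5,2.0,1
X,4.3,1.5,0
XI,2.3,0.8,0
XII,2.0,0.4,0
XIII,1.1,0.4,0
XIV,2.8,0.4,1
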