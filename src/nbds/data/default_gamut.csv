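name,c1,c2,c3,space
skin1,0.6228915974862301,0.6029477587087413,0.45380712942022505,xyz
skin2,0.5018326559220821,0.4816973595022989,0.34855183319081423,xyz
skin3,0.38736513381286736,0.3663283979842249,0.2512738929554381,xyz
skin4,0.2819912973924981,0.2633476413106728,0.17062498764587558,xyz
skin5,0.1885083952286999,0.1720889969023312,0.10005690714423471,xyz
skin6,0.1031391507299424,0.08996263372458752,0.04292630340413814,xyz
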