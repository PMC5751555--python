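patch_id,name,R,G,B
1,dark skin,115,82,68
2,light skin,194,150,130
3,blue sky,98,122,157
4,foliage,87,108,67
5,blue flower,133,128,177
6,bluish green,103,189,170
7,orange,214,126,44
8,purplish blue,80,91,166
9,moderate red,193,90,99
10,purple,94,60,108
11,yellow green,157,188,64
12,orange yellow,224,163,46
13,blue,56,61,150
14,green,70,148,73
15,red,175,54,60
16,yellow,231,199,31
17,magenta,187,86,149
18,cyan,8,133,161
19,white 9.5,243,243,242
20,neutral 8,200,200,200
21,neutral 6.5,160,160,160
22,neutral 5,122,122,121
23,neutral 3.5,85,85,85
24,black 2,52,52,52
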