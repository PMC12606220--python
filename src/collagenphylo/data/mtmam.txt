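A R N D C Q E G H I L K M F P S T W Y V
0 32 2 11 0 0 0 78 8 75 21 0 76 0 53 342 681 5 0 398
32 0 4 0 186 246 0 18 232 0 6 50 0 0 9 3 0 16 0 0
2 4 0 864 0 8 0 47 458 19 0 408 21 6 33 446 110 6 156 0
11 0 864 0 0 49 569 79 11 0 0 0 0 5 2 16 0 0 0 10
0 186 0 0 0 0 0 0 305 41 27 0 0 7 0 347 114 65 530 0
0 246 8 49 0 0 274 0 550 0 20 242 22 0 51 30 0 0 54 33
0 0 0 569 0 274 0 22 22 0 0 215 0 0 0 21 4 0 0 20
78 18 47 79 0 0 22 0 0 0 0 0 0 0 0 112 0 0 1 5
8 232 458 11 305 550 22 0 0 0 26 0 0 0 53 20 1 0 1525 0
75 0 19 0 41 0 0 0 0 0 232 6 378 57 5 0 360 0 16 2220
21 6 0 0 27 20 0 0 26 232 0 4 609 246 43 74 34 12 25 100
0 50 408 0 0 242 215 0 0 6 4 0 59 0 18 65 50 0 67 0
76 0 21 0 0 22 0 0 0 378 609 59 0 11 0 47 691 13 0 832
0 0 6 5 7 0 0 0 0 57 246 0 11 0 17 90 8 0 682 6
53 9 33 2 0 51 0 0 53 5 43 18 0 17 0 202 78 7 8 0
342 3 446 16 347 30 21 112 20 0 74 65 47 90 202 0 614 17 107 0
681 0 110 0 114 0 4 0 1 360 34 50 691 8 78 614 0 0 0 237
5 16 6 0 65 0 0 0 0 0 12 0 13 0 7 17 0 0 14 0
0 0 156 0 530 54 0 1 1525 16 25 67 0 682 8 107 0 14 0 0
398 0 0 10 0 33 20 5 0 2220 100 0 832 6 0 0 237 0 0 0
0.0692 0.0184 0.04 0.0186 0.0065 0.0238 0.0236 0.0557 0.0277 0.0905 0.1675 0.0221 0.0561 0.0611 0.0536 0.0725 0.087 0.0293 0.034 0.0428
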