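00000000000000000000
00000000011000000000
00000000111100000000
00000000111100000000
00000000111100000000
00000001111110000000
00000001111110000000
00000001111110000000
00000001111110000000
00000011111111000000
00000011100111000000
00000011100111000000
00000111100111100000
00000111000011100000
00000111000011100000
00001111000011110000
00001111111111110000
00001111111111110000
00001111111111110000
00011110000001111000
00011100000000111000
00011100000000111000
00111100000000111100
00111000000000011100
00111000000000011100
01111000000000011110
01110000000000001110
01110000000000001110
01110000000000001110
00000000000000000000
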