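00000000000000000000
00001111111111110000
00001111111111110000
00001111111111110000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00000000111100000000
00001111111111110000
00001111111111110000
00001111111111110000
00000000000000000000
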