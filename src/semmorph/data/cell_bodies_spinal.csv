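group;index;diameter_um;area_um2
1A;1;15,828;194,097
1A;2;12,518;121,758
1B;1;8,641;70,431
1B;2;8,106;51,446
1B;3;8,346;53,770
1B;4;7,146;37,265
1C;1;4,137;12,303
1C;2;3,273;8,799
1C;3;3,094;7,541
1C;4;4,030;12,303
1C;5;1,775;5,650
1C;6;1,367;1,553
1C;7;1,631;5,085
1C;8;4,101;13,679
1C;9;2,926;7,536
1C;10;2,950;7,360
1C;11;1,655;2,060
1C;12;1,751;2,257
1C;13;2,710;5,590
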