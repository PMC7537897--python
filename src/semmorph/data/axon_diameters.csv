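compartment;index;diameter_nm
brain;1;562
brain;2;594
brain;3;607
brain;4;608
brain;5;653
brain;6;690
brain;7;702
brain;8;746
brain;9;767
brain;10;780
brain;11;788
brain;12;808
brain;13;810
brain;14;815
brain;15;836
spinal_cord;1;552
spinal_cord;2;590
spinal_cord;3;605
spinal_cord;4;610
spinal_cord;5;629
spinal_cord;6;643
spinal_cord;7;643
spinal_cord;8;650
spinal_cord;9;661
spinal_cord;10;680
spinal_cord;11;712
spinal_cord;12;719
spinal_cord;13;765
spinal_cord;14;791
spinal_cord;15;831
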