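control_id,age,gender,dominant_hand,medication
1,64,Male,Right,None
2,70,Female,Right,None
3,62,Male,Right,None
4,65,Female,Right,None
5,67,Male,Right,None
6,68,Female,Right,None
7,72,Male,Right,None
8,63,Female,Right,None
9,69,Male,Right,None
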