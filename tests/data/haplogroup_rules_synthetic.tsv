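label	parent	motif
SA		1041:G
SB		2092:T
SC		3113:A
SD		4174:C
SE		5235:G
SA1'2	SA	1041:G;6301:T
SA1	SA1'2	1041:G;6301:T;6420:C
SA2	SA1'2	1041:G;6301:T;6533:A
SA3	SA	1041:G;7644:G
SA1a	SA1	1041:G;6301:T;6420:C;16066:A
SA1a1	SA1a	1041:G;6301:T;6420:C;16066:A;8755:T
SA1a2	SA1a	1041:G;6301:T;6420:C;16066:A;8866:G
SA1a3	SA1a	1041:G;6301:T;6420:C;16066:A;8977:C
SB1	SB	2092:T;9088:A
SB1a	SB1	2092:T;9088:A;9199:G
SB1b	SB1	2092:T;9088:A;9300:T
SB2'3'4	SB	2092:T;10411:C
SB2	SB2'3'4	2092:T;10411:C;10522:A
SB3	SB2'3'4	2092:T;10411:C;10633:G
SB3a	SB3	2092:T;10411:C;10633:G;11744:T
SB4	SB2'3'4	2092:T;10411:C;10855:C
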