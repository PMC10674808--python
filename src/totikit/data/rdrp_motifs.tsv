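motif	consensus	ref_position
I	KTGNPNT	400
II	GQPMSLT	440
III	SEHLIYA	480
IV	DFSKFDQ	520
V	SGQRATS	560
VI	YGDDSLI	600
VII	NTLLNAV	640
VIII	EFLRRHF	680
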