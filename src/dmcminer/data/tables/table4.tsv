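# Structures of the reference standards: hydroxy / methoxy substitution
# positions on the flavone (P-1, P-2, P-6, P-7, P-9) skeleton.  Mass weight is
# the printed nominal molecular weight of the neutral molecule.
label	name	formula	oh_positions	och3_positions	mass_weight
P-1	5-hydroxy-6,7,3',4'-tetramethoxyflavone	C_19_H_18_O_7_	5	6,7,3',4'	358
P-2	5-hydroxy-7,3',4'-trimethoxyflavone	C_18_H_16_O_6_	5	7,3',4'	328
P-6	5-hydroxy-6,7,8,3',4'-pentamethoxyflavone	C_20_H_20_O_8_	5	6,7,8,3',4'	388
P-7	5-hydroxy-6,7,3',4',5'-pentamethoxyflavone	C_20_H_20_O_8_	5	6,7,3',4',5'	388
P-9	5-hydroxy-6,7,8,3',4',5'-hexamethoxyflavone	C_21_H_22_O_9_	5	6,7,8,3',4',5'	418
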