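# Reference-standard identifications (positive mode): nine polymethoxyflavonoid
# standards with printed theoretical/experimental [M+H]+ m/z and MS^n strings.
# note=mass_formula_mismatch on P-3: the printed theoretical mass (375.12817) is
# inconsistent with the printed ion formula C20H19O7 (computed 371.11247); the
# row is transcribed as printed and excluded from mass-regression checks.
table	label	ion_mode	rt_min	ion_formula	theoretical_mz	experimental_mz	error_ppm	msn	reaction	note
1	P-1	P		C_19_H_19_O_8_	359.11256	359.11290	1.0	MS2[359]:326(100),344(71)|MS3[326]:298(100),278(0.6)
1	P-2	P		C_18_H_17_O_6_	329.10196	329.10123	-2.2	MS2[329]:314(100),313(66),285(21),268(4),192(0.5)|MS3[314]:283(100),298(37),167(24),270(24),173(2)
1	P-3	P		C_20_ H_19_O_7_	375.12817	375.12839	0.5	MS2[375]:211(100),191(18),357(13)|MS3[211]:196(100),183(29),178(29),150(22)		mass_formula_mismatch
1	P-4	P		C_20_H_23_O_7_	375.14382	375.14420	1.0	MS2[375]:211(100),191(43),357(20)|MS3[211]:196(100),178(24),183(9)
1	P-5	P		C_20_H_23_O_7_	375.14382	375.14420	1.0	MS2[375]:221(100),181(9)|MS3[221]:193(100),190(51),191(37),206(26)
1	P-6	P		C_20_ H_21_O_8_	389.12309	389.12289	-0.3	MS2[389]:359(100),328(70),374(66),356(42),328(15)|MS3[359]:344(100),341(72),343(66),191(39)
1	P-7	P		C_20_ H_21_O_8_	389.12309	389.12271	-0.9	MS2[389]:374(100),328(95),359(43),356(14)|MS3[374]:345(100),312(81),358(29),341(26)
1	P-8	P		C_21_H_25_O_8_	405.15439	405.15430	-0.2	MS2[405]:221(100),387(26),211(17)|MS3[221]:193(100),190(63),191(39),206(15)
1	P-9	P		C_20_ H_21_O_8_	419.13365	419.13360	-0.1	MS2[419]:389(100),404(66)|MS3[389]:356(100),371(90),361(85),359(79),374(79)		mass_formula_mismatch
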