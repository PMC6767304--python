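# Potential metabolites: MS1 accurate-mass hits whose MS^n spectra were never
# triggered, so no fragment strings exist and status is "potential".
table	label	ion_mode	rt_min	ion_formula	theoretical_mz	experimental_mz	error_ppm	msn	reaction	note
3	N1	P	10.78	C_15_H_11_O_6_	287.05497	287.05466	-1.2		Loss of 3CH_2_ + Demethoxylation
3	N2	P	8.46	C_16_H_13_O_6_	301.07062	301.07025	-1.3		Loss of 2CH_2_ + Demethoxylation
3	N3	P	6.98	C_17_H_15_O_6_	315.08627	315.08646	0.4		Loss of CH_2_ + Methoxylation
3	N4	P	8.84	C_17_H_15_O_6_	315.08627	315.08572	-1.8		Loss of CH_2_ + Methoxylation
3	N5	P	12.83	C_17_H_15_O_6_	315.08627	315.08624	-0.2		Loss of CH_2_ + Methoxylation
3	N6	P	8.78	C_18_H_19_O_6_	331.11761	331.11691	-2.1		Loss of OCH_2_ + Flavanone/Chalcone Formation
3	N7	P	7.96	C_17_H_17_O_7_	333.09697	333.09683	-0.1		Loss of 2CH_2_ + Flavanone/Chalcone Formation
3	N8	P	7.38	C_17_H_13_O_8_	345.06042	345.06033	-0.4		Loss of CH_4_ and CH_2_ + Oxidation
3	N9	P	10.03	C_19_H_21_O_9_	393.11797	393.11673	-3.2		Di-Oxidation + Flavanone/Chalcone Formation
3	N10	N	7.86	C_17_H_13_O_10_S	409.02237	409.02164	-1.8		Loss of 2CH_2_ + Sulfate Conjugation
3	N11	P	9.38	C_17_H_15_O_10_S	411.03802	411.03696	-2.6		Loss of 2CH_2_ +Sulfate Conjugation
3	N12	N	8.19	C_18_H_15_O_10_S	423.03802	423.03772	-0.7		Loss of CH_2_ + Sulfate Conjugation
3	N13	N	4.77	C_18_H_17_O_10_S	425.05472	425.05362	-0.1		Loss of CH_2_ + Flavanone/Chalcone Formation and Sulfate Conjugation
3	N14	P	5.36	C_19_H_21_O_10_S	441.08497	441.08429	-1.5		Flavanone/Chalcone Formation + Sulfate Conjugation
3	N15	N	6.84	C_23_H_21_O_13_	505.09767	505.09750	-0.3		Loss of 2CH_2_ + Glucuronide Conjugation
3	N16	P	6.81	C_23_H_23_O_13_	507.11332	507.11282	-0.9		Loss of 2CH_2_ + Glucuronide Conjugation
3	N17	P	7.21	C_24_H_27_O_12_	507.14971	507.14813	-3.1		Loss of OCH_2_ + Flavanone/Chalcone Formation and Glucuronide Conjugation
3	N18	P	5.57	C_24_H_23_O_13_	519.11332	519.11176	-3.0		Loss of CH_4_ + Glucuronide Conjugation
3	N19	P	6.74	C_24_H_25_O_14_	537.12387	537.12378	-0.1		Loss of CH_2_ + Oxidation and Glucuronide Conjugation
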