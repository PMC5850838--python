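	Mad	Ir	Weu	Ceu	Ger	Ibc	Nsw	Ssw	Spa	Cas	Mnma	Msma	Mrif	Mha
Mad	0.0	72.8	85.6	93.8	91.6	88.9	86.7	88.5	89.0	86.8	86.7	88.4	79.8	87.6
Ir	72.8	0.0	63.3	71.2	68.9	62.9	63.5	63.7	64.4	62.1	76.8	73.0	72.6	70.9
Weu	85.6	63.3	0.0	30.6	30.6	30.6	30.6	30.6	30.6	30.6	69.3	50.1	72.1	46.9
Ceu	93.8	71.2	30.6	0.0	30.6	30.6	30.6	30.6	30.6	30.6	75.6	51.5	74.9	46.8
Ger	91.6	68.9	30.6	30.6	0.0	37.1	40.2	34.1	42.8	40.1	70.8	58.8	72.1	54.9
Ibc	88.9	62.9	30.6	30.6	37.1	0.0	30.6	30.6	30.6	30.6	65.7	47.3	69.9	43.6
Nsw	86.7	63.6	30.6	30.6	40.2	30.6	0.0	30.6	30.6	30.6	68.1	50.2	68.9	46.4
Ssw	88.5	63.7	30.6	30.6	34.1	30.6	30.6	0.0	30.6	30.6	71.8	49.8	71.6	46.2
Spa	89.0	64.4	30.6	30.6	42.8	30.6	30.6	30.6	0.0	30.6	67.6	48.4	69.9	44.5
Cas	86.8	60.0	30.6	30.6	40.1	30.6	30.6	30.6	30.6	0.0	68.8	47.7	70.0	44.9
Mnma	86.7	76.8	69.3	75.6	70.8	65.7	68.1	71.8	67.6	68.8	0.0	57.7	68.0	63.9
Msma	88.4	73.1	50.1	51.5	58.8	47.3	50.2	49.8	48.4	47.7	57.7	0.0	68.3	55.6
Mrif	79.8	72.6	72.1	74.9	72.2	69.9	68.8	71.6	70.0	69.9	68.0	68.3	0.0	68.7
Mha	87.6	70.9	46.9	46.8	54.9	43.6	46.4	46.2	44.5	44.9	63.9	55.6	68.7	0.0
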