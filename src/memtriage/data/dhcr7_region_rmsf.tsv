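# Literature-reported region-summed RMSF values (A) for the DHCR7 wild type
# and ten variants, from replicate membrane MD simulations of a homology
# model. Region sums only; the cumulative discriminant is recomputed.
variant	group	TM1	TM2	TM3	TM4	TM5	TM6	TM7	TM8	TM9_10	CL1	CL2	CL3	CL4	CTD
T154R	pathogenic	22.9	17.6	15.5	9.1	14.5	17.4	17.2	17.8	31.6	53.1	48.6	8.8	78.8	30.8
E288K	pathogenic	19.6	16.4	16.0	10.5	13.1	14.3	16.0	18.4	26.1	49.2	38.6	13.6	77.5	32.0
T289I	pathogenic	25.2	18.0	17.8	12.8	14.1	14.3	19.5	17.5	28.7	50.1	47.9	10.1	71.1	30.4
G303R	pathogenic	21.1	18.9	16.8	11.0	13.3	16.0	18.2	17.0	30.2	50.5	49.2	10.4	65.0	30.1
R404C	pathogenic	23.4	16.5	16.0	10.8	16.0	16.8	20.8	23.3	31.6	48.9	57.4	10.0	80.1	32.7
V134L	unknown	20.1	21.1	18.8	11.0	14.7	13.6	16.6	16.2	27.7	52.9	53.4	11.0	79.7	35.6
R228Q	unknown	17.6	17.0	15.9	8.5	13.6	13.0	15.6	16.9	27.6	53.2	54.2	10.7	75.8	36.7
F361L	unknown	19.4	17.4	14.8	9.9	14.2	14.0	18.3	16.6	28.8	54.7	50.8	11.7	74.8	33.5
R260Q	non_pathogenic	19.7	18.6	15.5	9.4	12.9	14.6	15.4	17.2	24.4	58.4	52.1	11.4	79.3	28.1
A452T	non_pathogenic	20.9	19.6	17.8	10.5	13.6	16.2	16.4	17.2	26.0	55.2	52.8	8.7	66.6	30.1
WT	wild_type	18.2	18.3	17.9	10.7	16.3	16.0	18.5	18.1	31.1	51.9	65.1	13.0	80.4	37.8
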