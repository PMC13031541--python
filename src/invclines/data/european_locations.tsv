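location	latitude	longitude	temperature	n_SS	n_SN	n_NN
FK	68.09899	13.24322	4.5	2	18	27
LA	68.39371	14.47901	4.1	3	19	24
EG	68.30302	13.63961	4.9	4	23	18
OB	58.86962	5.56719	7.5	10	11	13
SK	58.69299	5.54701	7.6	3	14	14
OS	58.07161	6.64781	7.7	6	21	21
TJ	58.87095	11.11980	7.4	23	22	3
ST	56.76591	12.62948	7.3	8	27	8
RO	48.72543	-4.00535	11.4	32	4	0
VE	48.69565	-1.87943	11.8	24	7	11
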