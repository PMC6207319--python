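# Bimodal inter-blink-interval distributions observed by Ponder & Kennedy
# (peak locations and means, s) and the variable-threshold LIF parameter
# ranges that reproduce each pair of peaks (threshold trough a - k,
# period tau in s, corresponding frequency in Hz, and the median IBI of
# the matching simulated runs in s).
case	first_peak	second_peak	mean	a_minus_k_min	a_minus_k_max	tau_min	tau_max	freq_min	freq_max	median_min	median_max
1	0.5	3.5	2.05	0.14	0.19	4.0	7.0	0.14	0.25	2.42	2.73
2	0.5	5.0	3.31	0.14	0.16	6.0	8.5	0.12	0.16	3.45	3.86
3	0.5	5.0	3.64	0.14	0.16	6.0	8.5	0.11	0.16	3.45	3.86
4	0.5	6.5	4.12	0.15	0.16	8.0	8.5	0.11	0.13	4.65	4.91
5	1.0	5.5	3.95	0.30	0.35	6.5	9.0	0.11	0.15	3.95	4.65
6	0.5	7.0	4.45	0.15	0.15	9.0	9.0	0.11	0.11	5.03	5.03
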