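five_prime_dinuc	n	three_prime_1	three_prime_2	fold_change	ci_low	ci_high
GA	4	C	.	1112	1004	1185
AC	4	A	.	5.6	2.668	10.23
TC	4	G	.	129	.	.
GA	4	C	A	360	.	.
GA	4	C	G	2700	.	.
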