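# Published group summaries (mean, SD, n) of the NIH Toolbox cognitive
# battery for the two FNC-derived ADHD biotypes in the ABCD discovery cohort.
# Age-corrected T-scores; higher = better performance.
measure	n_biotype1	mean_biotype1	sd_biotype1	n_biotype2	mean_biotype2	sd_biotype2
PVT	821	105.97	15.81	248	101.62	15.37
LSWMT	821	98.74	14.30	248	94.70	14.52
DCCST	821	95.21	14.77	248	90.95	13.68
PCPST	821	91.62	22.42	248	84.66	22.14
PSMT	821	98.94	15.43	248	95.20	15.36
Fluid Cognition	821	92.72	17.00	248	85.98	16.32
Total Cognition	821	97.18	17.20	248	90.72	16.95
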