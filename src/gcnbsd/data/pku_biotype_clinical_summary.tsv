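# Published group summaries (mean, SD, n) of IQ and symptom scales for the
# two projected ADHD biotypes in the PKU validation cohort.
# RS_* = ADHD Rating Scale-IV; CPRS_* = Conners' Parent Rating Scale;
# PIQ = performance IQ (Wechsler). Higher symptom scores = more severe.
measure	n_biotype1	mean_biotype1	sd_biotype1	n_biotype2	mean_biotype2	sd_biotype2
RS_HI	89	18.64	4.27	41	22.22	5.16
RS_Total	89	45.14	6.79	41	48.82	6.42
PIQ	89	107.41	15.28	41	100.89	11.59
CPRS_IH	89	4.94	2.27	41	6.33	2.75
CPRS_H-Index	89	12.96	4.18	41	15.23	4.66
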