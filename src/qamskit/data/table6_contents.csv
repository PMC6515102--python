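sample,analyte,esm,esm_sd,qams,qams_sd
S1,gastrodin,5.23,0.16,,
S1,p-hydroxybenzyl alcohol,1.77,0.05,1.82,0.05
S1,parishin E,5.14,0.01,5.35,0.03
S1,p-hydroxy benzaldehyde,0.24,0.01,0.25,0.06
S1,parishin B,3.54,0.14,3.60,0.05
S1,parishin C,0.18,0.00,0.19,0.01
S1,parishin A,11.58,0.45,11.71,0.49
S2,gastrodin,4.51,0.38,,
S2,p-hydroxybenzyl alcohol,1.61,0.08,1.64,0.06
S2,parishin E,2.27,0.14,2.38,0.08
S2,p-hydroxy benzaldehyde,0.24,0.01,0.25,0.01
S2,parishin B,3.43,0.21,3.47,0.01
S2,parishin C,0.13,0.00,0.14,0.00
S2,parishin A,0.18,0.00,0.00,0.00
S3,gastrodin,2.44,0.28,,
S3,p-hydroxybenzyl alcohol,1.07,0.08,1.09,0.10
S3,parishin E,4.82,0.25,5.00,0.04
S3,p-hydroxy benzaldehyde,0.26,0.01,0.26,0.02
S3,parishin B,2.84,0.10,2.88,0.04
S3,parishin C,0.16,0.02,0.16,0.02
S3,parishin A,8.33,0.31,8.32,0.11
S4,gastrodin,1.35,0.02,,
S4,p-hydroxybenzyl alcohol,3.36,0.12,3.39,0.08
S4,parishin E,2.62,0.06,2.62,0.23
S4,p-hydroxy benzaldehyde,0.23,0.01,0.24,0.04
S4,parishin B,1.45,0.04,1.46,0.09
S4,parishin C,0.16,0.00,0.16,0.10
S4,parishin A,4.23,0.12,4.10,0.31
S5,gastrodin,3.41,0.38,,
S5,p-hydroxybenzyl alcohol,1.55,0.10,1.58,0.07
S5,parishin E,2.31,0.22,2.36,0.10
S5,p-hydroxy benzaldehyde,0.12,0.02,0.13,0.01
S5,parishin B,2.49,0.12,2.51,0.11
S5,parishin C,0.20,0.00,0.20,0.01
S5,parishin A,8.94,0.63,8.92,0.29
S6,gastrodin,1.91,0.12,,
S6,p-hydroxybenzyl alcohol,1.03,0.07,1.06,0.10
S6,parishin E,7.05,0.13,7.26,0.23
S6,p-hydroxy benzaldehyde,0.23,0.02,0.24,0.05
S6,parishin B,2.69,0.03,2.73,0.17
S6,parishin C,0.17,0.00,0.17,0.02
S6,parishin A,7.64,0.31,7.63,0.61
S7,gastrodin,3.12,0.01,,
S7,p-hydroxybenzyl alcohol,0.51,0.00,0.531,0.00
S7,parishin E,6.02,0.14,6.20,0.09
S7,p-hydroxy benzaldehyde,0.21,0.01,0.21,0.00
S7,parishin B,2.71,0.02,2.73,0.01
S7,parishin C,0.15,0.00,0.16,0.00
S7,parishin A,8.87,0.02,8.86,0.08
S8,gastrodin,3.06,0.10,,
S8,p-hydroxybenzyl alcohol,0.62,0.01,0.64,0.01
S8,parishin E,3.00,0.18,3.13,0.17
S8,p-hydroxy benzaldehyde,2.59,0.02,2.60,0.05
S8,parishin B,3.25,0.15,3.27,0.01
S8,parishin C,0.15,0.01,0.14,0.04
S8,parishin A,12.77,0.58,12.75,0.54
S9,gastrodin,2.85,0.37,,
S9,p-hydroxybenzyl alcohol,1.22,0.18,1.24,0.20
S9,parishin E,4.54,0.03,4.69,0.06
S9,p-hydroxy benzaldehyde,0.28,0.01,0.28,0.01
S9,parishin B,3.61,0.06,3.63,0.15
S9,parishin C,0.17,0.01,0.16,0.05
S9,parishin A,10.78,0.15,10.77,0.08
S10,gastrodin,5.89,0.22,,
S10,p-hydroxybenzyl alcohol,0.10,0.01,0.10,0.01
S10,parishin E,3.37,0.24,3.52,0.23
S10,p-hydroxy benzaldehyde,0.11,0.01,0.11,0.06
S10,parishin B,3.84,0.13,3.91,0.05
S10,parishin C,0.15,0.02,0.16,0.00
S10,parishin A,7.90,0.67,7.91,0.63
S11,gastrodin,4.74,0.37,,
S11,p-hydroxybenzyl alcohol,0.69,0.08,0.71,0.08
S11,parishin E,3.40,0.22,3.55,0.22
S11,p-hydroxy benzaldehyde,0.26,0.02,0.26,0.04
S11,parishin B,5.191,0.09,5.23,0.02
S11,parishin C,0.18,0.01,0.19,0.00
S11,parishin A,26.70,0.46,26.93,0.54
S12,gastrodin,7.10,0.27,,
S12,p-hydroxybenzyl alcohol,0.65,0.04,0.66,0.01
S12,parishin E,4.88,0.23,5.04,0.11
S12,p-hydroxy benzaldehyde,0.08,0.12,0.08,0.02
S12,parishin B,3.03,0.16,3.18,0.01
S12,parishin C,0.15,0.02,0.15,0.00
S12,parishin A,9.43,0.54,9.80,0.10
S13,gastrodin,4.03,0.03,,
S13,p-hydroxybenzyl alcohol,0.37,0.01,0.39,0.01
S13,parishin E,3.69,0.11,3.86,0.11
S13,p-hydroxy benzaldehyde,0.16,0.01,0.17,0.02
S13,parishin B,2.37,0.06,2.41,0.06
S13,parishin C,0.15,0.00,0.15,0.00
S13,parishin A,10.27,0.24,10.33,0.24
S14,gastrodin,2.59,0.03,,
S14,p-hydroxybenzyl alcohol,0.19,0.16,0.20,0.00
S14,parishin E,2.97,0.08,3.10,0.07
S14,p-hydroxy benzaldehyde,0.20,0.00,0.21,0.02
S14,parishin B,2.88,0.06,2.90,0.05
S14,parishin C,0.15,0.01,0.15,0.00
S14,parishin A,11.61,0.37,11.58,0.33
S15,gastrodin,4.29,0.15,,
S15,p-hydroxybenzyl alcohol,0.92,0.04,0.94,0.04
S15,parishin E,3.76,0.16,3.90,0.16
S15,p-hydroxy benzaldehyde,0.31,0.02,0.31,0.07
S15,parishin B,4.27,0.17,4.30,0.10
S15,parishin C,0.13,0.00,0.14,0.00
S15,parishin A,19.30,0.83,19.42,0.84
S16,gastrodin,6.48,0.21,,
S16,p-hydroxybenzyl alcohol,0.08,0.00,0.08,0.00
S16,parishin E,2.35,0.11,2.41,0.13
S16,p-hydroxy benzaldehyde,0.11,0.00,0.11,0.05
S16,parishin B,2.75,0.11,2.78,0.04
S16,parishin C,0.15,0.01,0.15,0.01
S16,parishin A,5.24,0.15,5.16,0.20
S17,gastrodin,5.09,0.39,,
S17,p-hydroxybenzyl alcohol,0.13,0.22,0.13,0.26
S17,parishin E,4.20,0.05,4.39,0.05
S17,p-hydroxy benzaldehyde,0.24,0.00,0.25,0.07
S17,parishin B,1.54,0.17,1.56,0.08
S17,parishin C,0.15,0.01,0.14,0.01
S17,parishin A,11.65,0.22,11.77,0.23
S18,gastrodin,3.71,0.05,,
S18,p-hydroxybenzyl alcohol,0.20,0.01,0.20,0.01
S18,parishin E,4.22,0.09,4.41,0.13
S18,p-hydroxy benzaldehyde,0.20,0.00,0.20,0.04
S18,parishin B,3.47,0.08,3.52,0.03
S18,parishin C,0.15,0.00,0.16,0.01
S18,parishin A,14.60,0.21,14.76,0.24
S19,gastrodin,0.42,0.01,,
S19,p-hydroxybenzyl alcohol,1.23,0.02,1.26,0.02
S19,parishin E,1.10,0.01,1.14,0.01
S19,p-hydroxy benzaldehyde,0.18,0.01,0.18,0.00
S19,parishin B,0.46,0.01,0.47,0.01
S19,parishin C,0.38,0.01,0.39,0.04
S19,parishin A,1.99,0.06,1.98,0.05
S20,gastrodin,0.36,0.02,,
S20,p-hydroxybenzyl alcohol,1.01,0.01,1.04,0.01
S20,parishin E,0.64,0.00,0.65,0.00
S20,p-hydroxy benzaldehyde,0.12,0.00,0.11,0.00
S20,parishin B,0.28,0.00,0.29,0.00
S20,parishin C,0.30,0.01,0.30,0.03
S20,parishin A,0.83,0.09,0.82,0.00
S21,gastrodin,1.50,0.14,,
S21,p-hydroxybenzyl alcohol,0.33,0.00,0.34,0.00
S21,parishin E,1.70,0.40,1.71,0.04
S21,p-hydroxy benzaldehyde,0.68,0.02,0.69,0.01
S21,parishin B,1.75,0.02,1.78,0.01
S21,parishin C,0.17,0.00,0.16,0.01
S21,parishin A,6.62,0.03,6.61,0.03
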