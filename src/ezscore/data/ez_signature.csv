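probeset,gene,cutpoint,chisq,p_value,hazard_ratio,prognostic
210841_s_at,NRP2,702,4.3,0.038,1.6,Bad
204364_s_at,REEP1,226,13,0.00028,2,Bad
205551_at,SV2B,53,4.6,0.032,1.5,Bad
43511_s_at,ARRB1,293,3.9,0.047,0.61,Good
211802_x_at,CACNA1G,302,4.4,0.035,0.5,Good
1555480_a_at,FBLIM1,73,5.1,0.024,0.66,Good
207822_at,FGFR1,240,5,0.026,0.51,Good
1552477_a_at,IRF6,111,4.4,0.035,0.55,Good
227297_at,ITGA9,34,13,0.00029,0.51,Good
235560_at,NOVA2,85,3.9,0.049,0.67,Good
228140_s_at,PPP2R2C,131,5.8,0.016,0.55,Good
206628_at,SLC5A1,175,4.3,0.038,0.63,Good
212560_at,SORL1,29,9.1,0.0026,0.52,Good
1559956_at,SYT7,65,5.8,0.016,0.64,Good
213869_x_at,THY1,110,4.2,0.039,0.67,Good
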