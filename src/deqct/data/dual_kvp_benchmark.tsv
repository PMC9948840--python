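material	mu_m_star_80	mu_m_star_130
adipose	0.964	0.982
breast	0.979	0.989
muscle	1.009	1.005
liver	1.009	1.003
bone_200	1.189	1.095
bone_800	1.547	1.271
bone_1250	1.708	1.350
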