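protein_id,construct,ph,d_rel,d_rel_se
alphaS,AH,7.4,0.65,0.17
alphaS,AH,3.5,0.48,0.07
alphaS,LF,7.4,1.00,0.00
alphaS,LF,3.5,0.91,0.20
alphaS,NAC,7.4,1.32,0.19
alphaS,NAC,3.5,0.71,0.13
alphaS,CT,7.4,1.01,0.14
alphaS,CT,3.5,0.36,0.07
betaS,AH,7.4,0.77,0.12
betaS,AH,3.5,0.41,0.09
betaS,LF,7.4,1.00,0.15
betaS,LF,3.5,0.49,0.07
betaS,NAC,7.4,1.36,0.18
betaS,NAC,3.5,0.60,0.08
betaS,CT,7.4,1.44,0.19
betaS,CT,3.5,0.33,0.05
gammaS,AH,7.4,0.49,0.09
gammaS,AH,3.5,0.71,0.23
gammaS,LF,7.4,1.22,0.20
gammaS,LF,3.5,1.11,0.16
gammaS,NAC,7.4,1.14,0.22
gammaS,NAC,3.5,1.01,0.20
gammaS,CT,7.4,1.65,0.23
gammaS,CT,3.5,1.19,0.18
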