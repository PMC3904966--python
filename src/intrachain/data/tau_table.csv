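protein_id,construct,ph,tau_r_us,tau_r_sd_us
alphaS,AH,7.4,2.08,0.47
alphaS,AH,3.5,2.35,0.19
alphaS,LF,7.4,1.10,0.11
alphaS,LF,3.5,1.20,0.18
alphaS,NAC,7.4,1.23,0.07
alphaS,NAC,3.5,1.48,0.05
alphaS,CT,7.4,1.37,0.08
alphaS,CT,3.5,2.44,0.35
betaS,AH,7.4,1.96,0.13
betaS,AH,3.5,2.42,0.42
betaS,LF,7.4,1.16,0.08
betaS,LF,3.5,1.81,0.07
betaS,NAC,7.4,0.84,0.03
betaS,NAC,3.5,1.59,0.09
betaS,CT,7.4,1.81,0.07
betaS,CT,3.5,2.50,0.20
gammaS,AH,7.4,2.41,0.30
gammaS,AH,3.5,1.36,0.39
gammaS,LF,7.4,1.14,0.11
gammaS,LF,3.5,1.05,0.06
gammaS,NAC,7.4,1.72,0.24
gammaS,NAC,3.5,1.40,0.20
gammaS,CT,7.4,1.14,0.05
gammaS,CT,3.5,0.98,0.05
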