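protein_id,construct,ph,eteff,eteff_sd
alphaS,AH,7.4,0.84,0.00
alphaS,AH,3.5,0.88,0.01
alphaS,LF,7.4,0.88,0.10
alphaS,LF,3.5,0.88,0.02
alphaS,NAC,7.4,0.82,0.00
alphaS,NAC,3.5,0.89,0.01
alphaS,CT,7.4,0.84,0.01
alphaS,CT,3.5,0.91,0.01
betaS,AH,7.4,0.83,0.01
betaS,AH,3.5,0.89,0.00
betaS,LF,7.4,0.87,0.01
betaS,LF,3.5,0.91,0.01
betaS,NAC,7.4,0.87,0.00
betaS,NAC,3.5,0.90,0.01
betaS,CT,7.4,0.71,0.01
betaS,CT,3.5,0.92,0.00
gammaS,AH,7.4,0.87,0.01
gammaS,AH,3.5,0.90,0.01
gammaS,LF,7.4,0.84,0.01
gammaS,LF,3.5,0.87,0.00
gammaS,NAC,7.4,0.78,0.01
gammaS,NAC,3.5,0.84,0.01
gammaS,CT,7.4,0.79,0.01
gammaS,CT,3.5,0.88,0.01
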