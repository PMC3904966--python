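protein_id,label,start,end
alphaS,AH,9,33
alphaS,LF,33,57
alphaS,NAC,59,83
alphaS,CT,92,115
betaS,AH,9,33
betaS,LF,35,59
betaS,NAC,59,83
betaS,CT,81,105
betaS,CT2,102,126
gammaS,AH,9,33
gammaS,LF,35,59
gammaS,NAC,59,83
gammaS,CT,92,117
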