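center_nm,width_nm,base_intensity,element,discriminative
247.86,0.12,0.60,C,0
279.55,0.10,0.85,Mg,1
280.27,0.10,0.70,Mg,1
285.21,0.10,0.75,Mg,1
288.16,0.10,0.30,Si,1
315.89,0.10,0.35,Ca,1
317.93,0.10,0.40,Ca,1
330.24,0.10,0.25,Na,1
388.34,0.25,0.90,CN,0
393.37,0.12,1.00,Ca,1
396.15,0.10,0.35,Al,1
396.85,0.12,0.95,Ca,1
403.08,0.10,0.40,Mn,1
404.58,0.10,0.30,Fe,1
422.67,0.12,0.90,Ca,1
430.25,0.20,0.35,CH,0
438.35,0.10,0.28,Fe,1
445.48,0.10,0.30,Ca,1
455.40,0.10,0.45,Ba,1
460.73,0.10,0.50,Sr,1
486.13,0.18,0.30,H,0
516.52,0.22,0.45,C2,0
518.36,0.10,0.40,Mg,1
558.87,0.10,0.35,Ca,1
588.99,0.12,0.95,Na,1
589.59,0.12,0.80,Na,1
610.27,0.10,0.30,Li,1
612.30,0.12,0.70,Ca,1
616.38,0.12,0.65,Ca,1
643.91,0.10,0.35,Ca,1
646.26,0.10,0.33,Ca,1
649.38,0.10,0.30,Ca,1
656.28,0.15,0.80,H,0
670.78,0.10,0.55,Li,1
742.36,0.12,0.30,N,0
744.23,0.12,0.35,N,0
746.83,0.12,0.40,N,0
766.49,0.14,1.00,K,1
769.90,0.14,0.85,K,1
777.30,0.14,0.55,O,0
818.33,0.10,0.25,Na,1
844.64,0.12,0.40,O,0
854.29,0.12,0.75,Ca,1
868.03,0.12,0.30,N,0
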