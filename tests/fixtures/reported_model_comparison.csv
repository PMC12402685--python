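model,deviance,daic,aicw
M0,89293.77,166.67,0.0
M1,89239.48,114.38,0.0
M2,89179.38,56.29,0.0
M3,89150.66,29.56,0.0
M4,89121.36,2.26,0.15
M5,89117.09,0.0,0.46
M6,89116.87,1.78,0.19
M7,89114.73,1.63,0.20
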