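structure,H,I,AZI,M1,M2,mM2,SDD
arabinose,4.3,10.9,71.6719,48,55,2.25,25.6667
galactose,5.2,13.2667,91.0625,59,68,2.7778,30.3333
maltose,10.2,27.4333,191.375,118,143,5.2222,58.3333
sucrose,10.4333,27.05,192.6094,116,138,5.4444,57.6667
sorbose,5.0875,12.2976,89.1006,60,71,2.7222,32
ribose,4.3667,11.0167,66.4375,48,56,2.3333,25
hmf,4.9,10.2,80,46,49,2.25,25
raffinose,14.3857,39.0143,271.3396,169,205,7.275,83.25
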