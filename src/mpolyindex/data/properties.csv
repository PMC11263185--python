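structure,density,bp,mp,mw,ws
arabinose,1.585,415.5,164,150.13,834
galactose,1.5,232.96,168,180.156,650
maltose,1.54,397.76,160,342.297,310
sucrose,1.587,697.1,186,342.30,200
sorbose,1.65,551.7,165,180,550
ribose,1.5,415.5,95,150.13,100
hmf,1.29,114,30,126.11,83
raffinose,884.8,363.0,81,504.44,229.8
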