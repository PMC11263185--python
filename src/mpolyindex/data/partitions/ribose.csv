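s,t,count
1,2,1
1,3,3
2,3,3
3,3,3
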