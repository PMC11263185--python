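s,t,count
1,2,3
1,3,5
2,3,9
3,3,7
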