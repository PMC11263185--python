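s,t,count
1,2,1
1,3,3
1,4,1
2,2,1
2,3,1
2,4,2
3,3,2
3,4,1
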