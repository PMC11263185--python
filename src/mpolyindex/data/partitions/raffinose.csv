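s,t,count
1,2,3
1,3,8
2,2,1
2,3,9
2,4,3
3,3,9
3,4,1
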