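label,mass,mass_type,representative_day
1w,1700,count,4
2w,9500,count,11
3w,15144,count,18
4w,13417,count,25
5w,9928,count,32
6w,6561,count,39
>7w,10699,count,46
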