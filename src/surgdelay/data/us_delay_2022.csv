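label,mass,mass_type,representative_day
1w,5399,count,4
2w,30159,count,11
3w,48075,count,18
4w,42592,count,25
5w,41619,count,32
6w,31422,count,39
7w,22234,count,46
8w,15319,count,53
9w,10295,count,60
10w,6804,count,67
11w,4449,count,74
12w,3014,count,81
>12w,8621,count,90
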