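format_version,zone,max_abs_rate_error
1,A,1.0
1,B,2.0
1,C,3.0
1,D,4.0
1,E,inf
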