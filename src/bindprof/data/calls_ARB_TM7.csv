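chain,res_seq,call
A,86,binding
A,89,binding
A,93,binding
A,177,binding
A,181,binding
A,240,binding
A,243,non_binding
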