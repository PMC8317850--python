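tp,fp,fn,tn
5987,1961,4700,5792
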