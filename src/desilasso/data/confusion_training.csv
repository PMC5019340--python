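truth,cancer,glands,stroma
cancer,9514,148,208
glands,207,33787,20
stroma,31,248,1110
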