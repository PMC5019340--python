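truth,cancer,glands,stroma
cancer,6448,284,25
glands,23,23814,17
stroma,3,98,523
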