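47e7e38774f6710c3568bb7bf28e4e6e592e49e07ce39b8c06d703c40d048821
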