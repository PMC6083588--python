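cancer,code
bowel,RES-B01
bowel,RES-B02
lung,RES-L01
lung,RES-L02
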