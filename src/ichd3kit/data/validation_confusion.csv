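,MO,MA,TTH,NOT_CLASSIFIABLE
MO,48,0,1,1
MA,0,14,0,0
TTH,9,1,24,0
NOT_CLASSIFIABLE,2,0,2,0
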