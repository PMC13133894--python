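# fixture: table6
# published real-time confusion matrix for binary clubbing-vs-normal classification
# evaluated on 3,700 images (1,956 clubbing, 1,744 normal); rows = actual, columns = predicted
actual,clubbing,normal
clubbing,1867,89
normal,79,1665
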