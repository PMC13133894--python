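# fixture: table12
# published confusion matrix for integrated four-level severity classification (3,700 images)
# rows = actual, columns = predicted
actual,normal,mild,moderate,severe
normal,1694,40,10,0
mild,10,598,42,2
moderate,8,34,588,22
severe,0,8,20,624
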