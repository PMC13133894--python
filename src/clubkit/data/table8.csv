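# fixture: table8
# published confusion matrix for anatomical landmark localization (1,956 clubbing images)
# rows = actual, columns = predicted
actual,nail_plate,nail_matrix,proximal_nail_fold
nail_plate,1888,39,29
nail_matrix,61,1794,101
proximal_nail_fold,42,46,1868
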