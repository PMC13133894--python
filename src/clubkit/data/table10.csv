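# fixture: table10
# published confusion matrix for landmark localization after augmentation-based training
# rows = actual, columns = predicted
actual,nail_plate,nail_matrix,proximal_nail_fold
nail_plate,1893,35,28
nail_matrix,50,1815,91
proximal_nail_fold,38,40,1878
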