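term,model,coef,pvalue
sequence,heteroskedastic,0.8419,<0.001
sequence_sq,heteroskedastic,-0.7427,<0.001
pc,heteroskedastic,-0.9930,<0.001
best,heteroskedastic,0.2424,<0.001
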