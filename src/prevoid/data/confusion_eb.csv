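# reference training confusion matrix, ensemble-bagging classifier
# rows: predicted state; columns: true state
state,empty,1/2,3/4,full
empty,665,56,11,2
1/2,49,598,93,42
3/4,21,71,426,135
full,8,35,136,433
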