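# reference training confusion matrix, stepwise linear-regression classifier
# rows: predicted state; columns: true state
state,empty,1/2,3/4,full
empty,657,61,19,10
1/2,54,586,103,65
3/4,23,77,413,135
full,9,36,131,402
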