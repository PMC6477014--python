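# reference training confusion matrix, support-vector (SMO) classifier
# rows: predicted state; columns: true state
state,empty,1/2,3/4,full
empty,681,53,14,5
1/2,36,601,98,59
3/4,19,71,438,129
full,7,35,116,419
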