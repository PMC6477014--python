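# reference training confusion matrix, three-classifier voting scheme
# rows: predicted state; columns: true state
state,empty,1/2,3/4,full
empty,712,27,7,1
1/2,19,642,84,51
3/4,9,65,463,127
full,3,26,112,433
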