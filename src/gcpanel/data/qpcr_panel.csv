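gene,cutoff,sensitivity,one_minus_specificity,auc
PGAP3,1.587158,0.067,0.034,0.249
LDLRAP1,1.479333,0.067,0.033,0.316
SNPH,0.966720,0.244,0.200,0.479
DDX54,1.806113,0.067,0.067,0.270
ABHD8,1.489475,0.111,0.200,0.353
FASN,1.555318,0.067,0.138,0.253
SNX2,1.216048,0.489,0.200,0.638
RHOT1,1.507539,0.467,0.200,0.704
EAF2,1.297566,0.489,0.200,0.631
ANXA1,1.123340,0.556,0.200,0.730
AIM2,1.306647,0.844,0.200,0.808
N4BP2L2,1.295575,0.200,0.200,0.627
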