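arm,t,S,risk
short_term,1,1,0
short_term,2,1,0
short_term,3,1,0
short_term,4,1,0
short_term,5,0.8571428571,0.1428571429
short_term,6,0.6857142857,0.3142857143
short_term,7,0.6857142857,0.3142857143
short_term,8,0.6857142857,0.3142857143
longer_term,1,1,0
longer_term,2,1,0
longer_term,3,1,0
longer_term,4,1,0
longer_term,5,0.6666666667,0.3333333333
longer_term,6,0.6666666667,0.3333333333
longer_term,7,0.6666666667,0.3333333333
longer_term,8,0.6666666667,0.3333333333
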