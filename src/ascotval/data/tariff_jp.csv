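domain_name,level,weight
control,1,1.000
control,2,0.954
control,3,0.089
control,4,0.000
cleanliness,1,0.734
cleanliness,2,0.686
cleanliness,3,0.236
cleanliness,4,0.141
food,1,0.875
food,2,0.807
food,3,0.247
food,4,0.086
safety,1,0.717
safety,2,0.385
safety,3,0.156
safety,4,0.089
participation,1,0.814
participation,2,0.759
participation,3,0.345
participation,4,0.033
occupation,1,1.018
occupation,2,0.975
occupation,3,0.218
occupation,4,0.134
accommodation,1,0.916
accommodation,2,0.825
accommodation,3,0.186
accommodation,4,0.052
dignity,1,0.704
dignity,2,0.347
dignity,3,0.059
dignity,4,0.000
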