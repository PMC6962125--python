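domain_name,level,weight
control,1,1.000
control,2,0.919
control,3,0.541
control,4,0.000
cleanliness,1,0.911
cleanliness,2,0.789
cleanliness,3,0.265
cleanliness,4,0.195
food,1,0.879
food,2,0.775
food,3,0.294
food,4,0.184
safety,1,0.880
safety,2,0.452
safety,3,0.298
safety,4,0.114
participation,1,0.873
participation,2,0.748
participation,3,0.497
participation,4,0.241
occupation,1,0.962
occupation,2,0.927
occupation,3,0.567
occupation,4,0.170
accommodation,1,0.863
accommodation,2,0.780
accommodation,3,0.374
accommodation,4,0.288
dignity,1,0.847
dignity,2,0.637
dignity,3,0.295
dignity,4,0.263
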