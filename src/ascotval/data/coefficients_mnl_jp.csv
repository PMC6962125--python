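term,domain_name,level,estimate,se
domain,accommodation,,0.2124,0.0572
domain,safety,,0.3620,0.0585
domain,food,,0.3487,0.0602
domain,cleanliness,,0.5743,0.0566
domain,participation,,0.1330,0.0553
domain,dignity,,0.0005,0.0576
domain,occupation,,0.5452,0.0582
level,accommodation,1,3.5226,0.0635
level,accommodation,2,3.1502,0.0634
level,accommodation,3,0.5459,0.0562
level,safety,1,2.5613,0.0625
level,safety,2,1.2074,0.0587
level,safety,3,0.2753,0.0569
level,food,1,3.2185,0.0645
level,food,2,2.9394,0.0637
level,food,3,0.6573,0.0572
level,cleanliness,1,2.4154,0.0617
level,cleanliness,2,2.2212,0.0623
level,cleanliness,3,0.3894,0.0567
level,control,1,4.0760,0.0586
level,control,2,3.8895,0.0584
level,control,3,0.3610,0.0545
level,participation,1,3.1844,0.0615
level,participation,2,2.9607,0.0618
level,participation,3,1.2745,0.0579
level,dignity,1,2.8675,0.0643
level,dignity,2,1.4144,0.0592
level,dignity,3,0.2387,0.0566
level,occupation,1,3.6034,0.0641
level,occupation,2,3.4306,0.0637
level,occupation,3,0.3436,0.0564
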