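region,mu_a,lambda_a
1,229,536
2,748,1774
3,892,1680
4,587,1154
5,882,1914
6,270,378
7,461,1008
8,436,690
9,220,735
10,548,1040
11,590,1089
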