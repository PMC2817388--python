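variable,odds_ratio,p_value
CD3-DR-CD56+CD16+,0.183,0.008
Lin-DR-,0.228,0.018
CD45+CD3+,0.274,0.035
CD3+CD8+CD38+CD28+,0.281,0.047
CD3-CD8+,0.323,0.084
CD3-DR+CD56+CD16+,0.339,0.087
CD3+CD8-CD7+CD154+,0.339,0.087
CD3-DR-CD56-CD16-,0.364,0.113
CD3+CD8+CD7+CD154+,0.388,0.463
CD3+CD8-CD7+CD154-,0.389,0.146
CD3+CD8-DR+CD95-,0.429,0.189
CD3+DR-,0.460,0.236
CD3+CD8-CD45RA+CD62L+,0.477,0.283
CD3+CD8-DR+CD95+,0.477,0.283
CD45-CD3+,0.494,0.632
CD3+CD8-,0.494,0.632
Lin-DR+CD123+CD11c+,0.564,0.424
CD3+CD8+DR+CD95+,0.628,0.571
CD3-DR+,0.646,0.586
CD3+CD8-DR-CD95-,0.646,0.586
CD45+CD3+CD8-CD4-,0.703,0.690
CD3+CD8+CD38-CD28+,0.709,0.699
CD3+CD8-CD7-CD154-,0.740,0.774
CD3+CD8+,0.752,0.786
CD3+CD8-CD38+CD28+,0.759,0.797
CD3+CD8+CD38+CD28-,0.760,0.812
CD3-DR+CD56-CD16-,0.805,0.887
CD3-DR+CD56+CD16-,0.805,0.887
CD3+CD8+CD38-CD28-,0.813,0.898
CD45-CD3-,0.862,0.989
Lin-DR+CD123+CD11c-,0.913,0.917
CD3+CD8+CD45RA+CD62L-,0.923,0.908
CD3+CD8+CD45RA-CD62L,0.931,0.898
CD45+CD3+CD8-CD4+,0.931,0.898
CD3+CD8+DR+CD95-,0.938,0.887
CD3+CD8-CD7-CD154+,0.962,0.696
CD3+CD8-CD38+CD28-,0.996,0.797
CD3+CD8+DR-CD95-,1.004,0.797
Lin+DR+,1.074,0.898
CD3-DR-CD56-CD16+,1.074,0.898
CD3-CD8-,1.074,0.898
Lin+DR-,1.149,1.000
CD45+CD3-,1.160,0.989
CD3+CD8-CD38-CD28-,1.160,0.989
CD3+CD8-CD45RA+CD62L-,1.230,0.898
CD45+CD3+CD8+CD4-,1.317,0.797
CD3+DR+,1.329,0.786
Lin-DR+CD123-CD11c-,1.329,0.786
CD3+CD8-DR-CD95+,1.329,0.786
CD3+CD8+DR-CD95+,1.410,0.699
CD45+CD3+CD8+CD4+,1.410,0.699
CD3+CD8+CD45RA-CD62L+,1.422,0.690
CD3-DR-,1.446,0.677
CD3-DR+CD56-CD16+,1.486,0.661
Lin-DR+,1.511,0.605
CD4+,1.522,0.598
Lin-DR+CD123-CD11c+,1.522,0.598
CD3+CD8-CD45RA-CD62L+,1.630,0.512
CD3-DR-CD56+CD16-,1.630,0.512
CD3+CD8+CD7+CD154-,1.657,0.502
CD3+CD8+CD7-CD154-,1.707,0.487
CD3+CD8-CD38-CD28+,1.898,0.354
CD3+CD8-CD45RA-CD62L,2.011,0.294
CD3+CD8+CD45RA+CD62L+,2.152,0.238
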