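field,positive_mean,positive_sd,negative_mean,negative_sd
age_years,46.3,12.7,45.8,10.7
sds_score,10.93,3.33,10.31,3.28
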