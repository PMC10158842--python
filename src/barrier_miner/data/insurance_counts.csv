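bucket,count
no_insurance,40
treatment_not_covered,44
fear_of_losing_coverage,8
forced_treatment_switch,5
general_insurance_difficulty,68
multiple,13
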