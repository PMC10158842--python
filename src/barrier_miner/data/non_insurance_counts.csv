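bucket,count
financial_difficulty,22
stigma,40
provider_issues,4
poor_treatment_by_clinician_or_pharmacist,3
fear_of_starting_treatment,1
multiple,14
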