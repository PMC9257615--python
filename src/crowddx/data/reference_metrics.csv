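disease_category,n_reference_positive,precision,recall,f1,accuracy
cardiovascular,82,0.92,0.74,0.82,0.94
endocrine,19,0.75,0.63,0.69,0.97
gastrointestinal,18,0.56,0.56,0.56,0.96
genitourinary,35,0.97,0.80,0.88,0.98
infections,30,0.56,0.77,0.65,0.94
injuries_external,53,0.69,0.92,0.79,0.94
mental_health,20,0.48,0.70,0.57,0.95
musculoskeletal,45,0.64,0.51,0.57,0.91
neoplasms,162,0.95,0.98,0.96,0.97
nervous_system,66,0.88,0.42,0.57,0.90
respiratory,29,0.92,0.76,0.83,0.98
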