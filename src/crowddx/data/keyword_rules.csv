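pattern,disease_category
accident,injuries_external
injury,injuries_external
injuries,injuries_external
injured,injuries_external
crash,injuries_external
collision,injuries_external
burn,injuries_external
burns,injuries_external
burned,injuries_external
heart transplant,cardiovascular
heart surgery,cardiovascular
chemo,neoplasms
chemotherapy,neoplasms
radiation,neoplasms
radiotherapy,neoplasms
bone marrow transplant,neoplasms
dialysis,genitourinary
kidney transplant,genitourinary
renal transplant,genitourinary
liver transplant,gastrointestinal
lung transplant,respiratory
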