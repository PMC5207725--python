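name,bddcs_class,percent_metabolised_human,major_cyps,human_metabolised,trout_observed_metabolised,notes
Atenolol,3,6.00,2D6,False,False,
Carbamazepine,2,99.50,3A4,True,False,
Diazepam,1,99.50,2C19;3A4,True,False,
Diclofenac sodium salt,1,99.50,2C9;2C8;2C18;2C19;2B6,True,True,Believed to be principally 2C and likely 2C9; several minor enzymes (2C8 2C18 2C19 2B6) producing a wide range of metabolites
Metoprolol succinate,1,99.00,2D6,True,False,
Phenylbutazone,1,99.00,2D6;2C19;3A4,True,True,
Propranolol HCl,1,99.75,1A2;2D6,True,True,
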