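source,category
Glucose,sugars
Ribose,sugars
Cellobiose,sugars
Raffinose,sugars
Glycerol,sugar alcohols
Mannitol,sugar alcohols
Sorbitol,sugar alcohols
Acetate,carboxylate ions
Citrate,carboxylate ions
Succinate,carboxylate ions
Alanine,amino acids
Glutamine,amino acids
Isoleucine,amino acids
Proline,amino acids
Serine,amino acids
Uridine,nucleic acids
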