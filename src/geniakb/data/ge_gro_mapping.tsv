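# Equivalence mappings between Genia (GE'13) and GRO ('13) concepts.
# Columns: Genia concept <TAB> GRO concept.  Protein maps to both Gene and
# Protein in GRO; the forward (GE->GRO) direction resolves the one-to-many
# choice via configuration (default: Protein).
Acetylation	Acetylation
Binding	BindingToProtein
Gene_expression	GeneExpression
Localization	Localization
Negative_regulation	NegativeRegulation
Phosphorylation	Phosphorylation
Positive_regulation	PositiveRegulation
Protein	Gene
Protein	Protein
Protein_catabolism	ProteinCatabolism
Protein_modification	ProteinModification
Regulation	RegulatoryProcess
Transcription	Transcription
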