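# SYNTHETIC toy is-a hierarchy over GRO concept names (child <TAB> parent).
# Hand-built to cover the concepts exercised by the converter and its tests;
# it is NOT the published Gene Regulation Ontology, only a small stand-in
# with the same subsumption paths for the covered concepts.
Continuant	Entity
Occurrent	Entity
PhysicalContinuant	Continuant
LivingEntity	PhysicalContinuant
Organism	LivingEntity
Eukaryote	Organism
Cell	LivingEntity
Tissue	PhysicalContinuant
CellComponent	PhysicalContinuant
MolecularEntity	PhysicalContinuant
InformationBiopolymer	MolecularEntity
NucleicAcid	InformationBiopolymer
DNA	NucleicAcid
Gene	NucleicAcid
ProteinDomain	InformationBiopolymer
Protein	InformationBiopolymer
TranscriptionRegulator	Protein
TranscriptionFactor	TranscriptionRegulator
Enzyme	Protein
ProteinSubunit	Protein
Chemical	MolecularEntity
OrganicChemical	Chemical
AminoAcid	OrganicChemical
Process	Occurrent
Increase	Process
Disease	Process
Mutation	Process
PhysicalInteraction	Process
Binding	PhysicalInteraction
BindingOfProteinToDNA	Binding
BindingOfTranscriptionFactorToDNA	BindingOfProteinToDNA
BindingToProtein	Binding
Heterodimerization	BindingToProtein
MolecularProcess	Process
Pathway	MolecularProcess
SignalingPathway	Pathway
GeneExpression	MolecularProcess
Transcription	GeneExpression
TranscriptionOfGene	Transcription
ProteinModification	MolecularProcess
Acetylation	ProteinModification
Phosphorylation	ProteinModification
ProteinCatabolism	MolecularProcess
Localization	MolecularProcess
Transport	Localization
ProteinTransport	Transport
ProteinTargeting	ProteinTransport
RegulatoryProcess	MolecularProcess
PositiveRegulation	RegulatoryProcess
NegativeRegulation	RegulatoryProcess
RegulationOfGeneExpression	RegulatoryProcess
PositiveRegulationOfGeneExpression	RegulationOfGeneExpression
RegulationOfTranscription	RegulatoryProcess
NegativeRegulationOfTranscription	RegulationOfTranscription
PositiveRegulationOfTranscription	RegulationOfTranscription
CellGrowth	Process
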