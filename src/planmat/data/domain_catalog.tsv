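domain_id	role	categories	keep_list	description
IPR008160	defining	core	1	Collagen triple helix repeat
IPR000885	defining	core	1	Fibrillar collagen C-terminal domain
IPR001791	defining	core	0	Laminin G domain
IPR002049	defining	core	0	Laminin EGF domain
IPR002035	defining	core	0	von Willebrand factor type A domain
IPR001846	defining	core	0	von Willebrand factor type D domain
IPR001007	defining	core	0	von Willebrand factor type C domain
IPR000884	defining	core	0	Thrombospondin type-1 repeat
IPR003886	defining	core	0	NIDO domain
IPR018933	defining	core	0	Netrin module C345C
IPR001073	defining	affiliated	0	C1q domain
IPR001304	defining	affiliated	0	C-type lectin domain
IPR001079	defining	affiliated	0	Galectin carbohydrate recognition domain
IPR000922	defining	affiliated	0	SUEL-type lectin domain
IPR001818	defining	regulator	1	Peptidase M10 metallopeptidase domain
IPR000215	defining	regulator	0	Serpin family
IPR001134	defining	regulator	0	Netrin NTR domain
IPR002350	defining	regulator	0	Kazal domain
IPR002007	defining	regulator	0	Animal haem peroxidase domain
IPR002919	defining	regulator	0	Trypsin inhibitor-like cysteine-rich domain
IPR000010	defining	regulator	0	Cystatin domain
IPR020067	defining	regulator	0	Fringe-like glycosyltransferase domain
IPR005817	defining	secreted	0	Wnt family
IPR001839	defining	secreted	0	Transforming growth factor-beta family
IPR002209	defining	secreted	0	Heparin-binding growth factor family
IPR016179	defining	secreted	0	Insulin-like peptide
IPR000719	excluding	all	0	Protein kinase domain
IPR000242	excluding	all	0	Protein tyrosine phosphatase domain
IPR000276	excluding	all	0	G protein-coupled receptor rhodopsin-like 7TM
IPR000413	excluding	all	0	Integrin alpha chain
IPR001849	excluding	all	0	Pleckstrin homology domain
IPR000504	excluding	all	0	RNA recognition motif
IPR002919	excluding	core	0	Trypsin inhibitor-like cysteine-rich domain
IPR001073	excluding	core	0	C1q domain
IPR002350	excluding	core,secreted	0	Kazal domain
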