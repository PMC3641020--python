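symbol	description
ACE2	angiotensin I converting enzyme 2
ADD1	adducin 1
ADIPOQ	adiponectin, C1Q and collagen domain containing
ADRA2B	adrenergic, alpha-2B-, receptor
ADRB1	adrenergic, beta-1-, receptor
ADRB2	adrenergic, beta-2-, receptor, surface
AGT	angiotensinogen
AGTR1	angiotensin II receptor, type 1
ALDH2	aldehyde dehydrogenase 2 family
ATP1A1	ATPase, Na+/K + transporting, alpha 1 polypeptide
ATP1B1	ATPase, Na+/K + transporting, beta 1 polypeptide
BDKRB2	bradykinin receptor B2
CACNA1C	calcium channel, voltage-dependent, L type, alpha 1C subunit
CACNA1D	calcium channel, voltage-dependent, L type, alpha 1D subunit
CALCA	calcitonin-related polypeptide alpha
CHGA	chromogranin A
CLCNKB	chloride channel Kb
CYBA	cytochrome b-245, alpha polypeptide
CYP11B2	cytochrome P450, family 11, subfamily B, polypeptide 2
CYP19A1	cytochrome P450, family 19, subfamily A, polypeptide 1
CYP2J2	cytochrome P450, family 2, subfamily J, polypeptide 2
CYP4A11	cytochrome P450, family 4, subfamily A, polypeptide 11
CYP4F2	cytochrome P450, family 4, subfamily F, polypeptide 2
EMILIN1	elastin microfibril interfacer 1
FABP3	fatty acid binding protein 3
FBN1	fibrillin 1
FURIN	furin (paired basic amino acid cleaving enzyme)
GDF15	growth differentiation factor 15
GNB3	guanine nucleotide binding protein, beta polypeptide 3
GRK4	G protein-coupled receptor kinase 4
GSTM3	glutathione S-transferase mu 3 (brain)
GUCA2B	guanylate cyclase activator 2B
HMOX1	heme oxygenase 1
HSD3B1	hydroxy-delta-5-steroid dehydrogenase, 3 beta- and steroid delta-isomerase 1
HSPA4	heat shock 70 kDa protein 4
IL10	interleukin 10
IL6	interleukin 6
KL	klotho
KLK1	kallikrein 1
KLKB1	kallikrein B, plasma 1
KNG1	kininogen 1
MTHFR	5,10-methylenetetrahydrofolate reductase
NEDD4L	neural precursor cell expressed, developmentally down-regulated 4-like
NOS3	nitric oxide synthase 3
NPPB	natriuretic peptide precursor B
NPR1	natriuretic peptide receptor A/guanylate cyclase A
NR3C2	nuclear receptor subfamily 3, group C, member 2
P2RY2	purinergic receptor P2Y, G-protein coupled, 2
PNMT	phenylethanolamine N-methyltransferase
PPARG	peroxisome proliferator-activated receptor gamma
PSMA6	proteasome subunit, alpha type, 6
PTGER2	prostaglandin E receptor 2
PTK2B	PTK2B protein tyrosine kinase 2 beta
PTPN1	protein tyrosine phosphatase, non-receptor type 1
REN	renin
RNLS	renalase, FAD-dependent amine oxidase
SCNN1A	sodium channel, nonvoltage-gated 1 alpha
SCNN1B	sodium channel, nonvoltage-gated 1, beta
SELE	selectin E
SLC6A9	solute carrier family 6, member 9
SLC7A1	solute carrier family 7, member 1
SLCO1B1	solute carrier organic anion transporter family, member 1B1
SOD3	superoxide dismutase 3, extracellular
TGFB1	transforming growth factor, beta 1
TH	tyrosine hydroxylase
TNFRSF4	tumor necrosis factor receptor superfamily, member 4
VEGFA	vascular endothelial growth factor A
WNK1	WNK lysine deficient protein kinase 1
WNK4	WNK lysine deficient protein kinase 4
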