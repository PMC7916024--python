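gene_id	description	regulation
BTG2	BTG anti-proliferation factor 2	up
EED	embryonic ectoderm development	up
HBP1	HMG-box transcription factor 1	up
PTGS2	prostaglandin-endoperoxide synthase 2	up
NAMPT	nicotinamide phosphoribosyltransferase	up
ATP6V0A1	ATPase H+ transporting V0 subunit a1	up
EAF2	ELL associated factor 2	up
LONP1	lon peptidase 1, mitochondrial	down
RALY	RALY heterogeneous nuclear ribonucleoprotein	down
PACS2	phosphofurin acidic cluster sorting protein 2	down
SH2D2A	SH2 domain containing 2A	down
DGKZ	diacylglycerol kinase zeta	down
MEPCE	methylphosphate capping enzyme	down
KCTD13	potassium channel tetramerization domain containing 13	down
ELF4	E74 like ETS transcription factor 4	down
MFSD10	major facilitator superfamily domain containing 10	down
MAZ	MYC associated zinc finger protein	down
SIGIRR	single Ig and TIR domain containing	down
FCHO1	FCH domain only 1	down
BCR	BCR, RhoGEF and GTPase activating protein	down
PPRC1	peroxisome proliferator-activated receptor gamma, coactivator-related 1	down
TPM2	tropomyosin 2	down
IDUA	iduronidase, alpha-L-	down
PFN1	profilin 1	down
LMF2	lipase maturation factor 2	down
FLNA	filamin A	down
APRT	adenine phosphoribosyltransferase	down
SLC10A3	solute carrier family 10 member 3	down
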