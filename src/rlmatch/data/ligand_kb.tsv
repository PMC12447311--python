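# Neurotrophic receptor -> ligand knowledgebase (curated fixture).
# The five pairings with commercially available recombinant ligands used for
# medium supplementation (TRKB/NTRK2-BDNF, CNTFR-CNTF, GFRA1-GDNF, GFRA2-NRTN,
# GFRA3-PSPN) carry ligand_available=true and a 50 ng/mL working concentration
# in notes. Remaining rows are plausible padding for the other curated
# neurotrophic receptors; availability=false models pairings without a
# practical recombinant supplement.
receptor_symbol	receptor_accession	ligand_name	ligand_available	notes
NTRK2	Q16620	BDNF	true	TRKB; working concentration 50 ng/mL
CNTFR	P26992	CNTF	true	working concentration 50 ng/mL
GFRA1	P56159	GDNF	true	working concentration 50 ng/mL
GFRA2	O00451	NRTN	true	neurturin; working concentration 50 ng/mL
GFRA3	O60609	PSPN	true	persephin; working concentration 50 ng/mL
NTRK3	Q16288	NT3	true	TRKC; conventional supplement together with BDNF
NTRK1	P04629	NGF	true	TRKA
NGFR	P08138	proNGF	false	p75NTR; pan-neurotrophin co-receptor
GFRA4	Q9GZZ7	PSPN	false	redundant with GFRA3 pairing in supplementation
RET	P07949	GDNF	false	signals via GFRA co-receptors; covered by GDNF-family ligands
LIFR	P42702	LIF	false	not used for neuronal supplementation here
IL6ST	P40189	IL27	false	gp130 shared subunit; no dedicated supplement
OSMR	Q99650	OSM	false	oncostatin M
MET	P08581	HGF	false	hepatocyte growth factor
SORT1	Q99523	proBDNF	false	sortilin; pro-neurotrophin co-receptor
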