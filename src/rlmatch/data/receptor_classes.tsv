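# Curated receptor-class list (synthetic curation assembled for this package):
# 29 growth-factor receptors of which 15 are neurotrophic-signaling receptors.
# Includes every receptor the analysis must recognize by name (TRKB/NTRK2,
# TRKC/NTRK3, CNTFR, GFRA1-4, FGFR1, ...); the remainder are standard RTK /
# cytokine-receptor family members. receptor_class: growth_factor | neurotrophic.
# This list overrides keyword-derived flags on conflict and is versioned with
# the package because every funnel count downstream depends on it.
gene_symbol	accession	receptor_class
NTRK1	P04629	neurotrophic
NTRK2	Q16620	neurotrophic
NTRK3	Q16288	neurotrophic
NGFR	P08138	neurotrophic
GFRA1	P56159	neurotrophic
GFRA2	O00451	neurotrophic
GFRA3	O60609	neurotrophic
GFRA4	Q9GZZ7	neurotrophic
RET	P07949	neurotrophic
CNTFR	P26992	neurotrophic
LIFR	P42702	neurotrophic
IL6ST	P40189	neurotrophic
OSMR	Q99650	neurotrophic
MET	P08581	neurotrophic
SORT1	Q99523	neurotrophic
FGFR1	P11362	growth_factor
FGFR2	P21802	growth_factor
FGFR3	P22607	growth_factor
FGFR4	P22455	growth_factor
EGFR	P00533	growth_factor
ERBB2	P04626	growth_factor
ERBB3	P21860	growth_factor
IGF1R	P08069	growth_factor
INSR	P06213	growth_factor
PDGFRA	P16234	growth_factor
PDGFRB	P09619	growth_factor
KDR	P35968	growth_factor
KIT	P10721	growth_factor
TGFBR2	P37173	growth_factor
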