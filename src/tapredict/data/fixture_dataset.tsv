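# tapredict fixture dataset version 1.0
# deterministic reconstruction; see docs/methods.md for provenance
id	name	organism	location	cterm_seq	tmd_start	tmd_end	source
acbd5	ACBD5	human	PO	SPGVLTFAIIWPFIAQWLVYLYYQRRRRKLN	1	23	TMD-tail peptide from the experimental mutant series (verified sequence)
faldh_po	FALDH-PO	human	PO	SSGSSGSSGSLLLAAAAAAAAAAAAAAALLLQRRRRRRRRRHAQNA	11	31	synthetic emulation of reported physicochemical properties (unverified membership); tail charge set to the reported value
faldh_er	FALDH-ER	human	ER	SSGSSGSSGSLLLAAAAAAAAAAAAAAALLLQAEALQLN	11	31	synthetic emulation of reported physicochemical properties (unverified membership); tail charge set to the reported value
acbd4	ACBD4	human	PO	SGSSSGSGSGAAAAAAAAAAGAAAAAAAAAAQRRRANQQRANR	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
pex26	PEX26	human	PO	SSSGSSGSSSAAAAAAAAAAAAAAAAAAAALQNRQRNQNQANAQRQANQRRAA	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
fis1	FIS1	human	PO_MITO	SSGSSGSSSGAAAAAAAAAAAAAAAAAAAAAQAARQNRNQR	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
gdap1	GDAP1	human	PO_MITO	SSSGSGSGSSLAAAAAAAAAAAAAAAAAAAAQRQQAQRNARQNNA	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
mff	MFF	human	PO_MITO	SSGSSGSSSSLAAAAAAAAAAAAAAAAAAAAQNANNRRQAAQQ	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
bclxl	BCLXL	human	PO_MITO	GSSSSGSSSSLAAAAAAAAAAAAAAAAAAALQQRRQRAANN	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
miro1	MIRO1	human	PO_MITO	SSGGSSSGSSAAAAAAAAAAAAAAAAAAAAAQANAQNAAQRNNQRQQ	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
omp25	OMP25	human	PO_MITO	SSSGGSSGSSLAAAAAAAAAAAAAAAAAAAAQQRQQQANRRANNA	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
bcl2	BCL2	human	PO_MITO_ER	GSGSGGSSSSLAAAAAAAAAAAAAAAAAALLQNQAQNRQRA	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
miro2	MIRO2	human	PO_MITO_ER	GSSGSSSSSGAAAAAAAAAAAAAAAAAAAALQAQAQQANRRNQNNAQ	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
bak	BAK	human	MITO	SSSGSSSSGGAAAAAAAAAAAAAAAAAAAAAQQANAQRNQR	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
bax	BAX	human	MITO	SSSGSSGGSSAAAAAAAAAAGAAAAAAAAAAQQNAQQARAN	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
maoa	MAOA	human	MITO	SGSSSGSSGSAAAAAAAAAAAAAAAAAAAAAQANQARRQNAQN	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
tomm22	TOMM22	human	MITO	SSSGSGSGSSLLLAAAAAAAAAAAAAALLLLQQANNQNAQAQA	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
sec61b	SEC61B	human	ER	SGSGSSSGSSLLAAAAAAAAAAAAAAAAALLQRNAQAQN	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
vapb	VAPB	human	ER	SSGSSSSGGGLLAAAAAAAAAAAAAAAALLLQQQANA	11	31	synthetic emulation of reported physicochemical properties (unverified membership)
synth_po_01	synth_po_01	human	PO	SSGSSGSSSSLLAAAAAAAAAAAAAAAALLLQRRRRRNRARQRRQRRR	11	31	synthetic filler matching group feature distribution
synth_po_02	synth_po_02	human	PO	SGGSSGSSSSAAAAAAAAAAGAAAAAAAAAAQQANRRQRRNRNQAAQRRR	11	31	synthetic filler matching group feature distribution
synth_po_03	synth_po_03	human	PO	GGGGGSSSSGLAAAAAAAAAAAAAAAAAAALQQNNRQRARQNRAQRRA	11	31	synthetic filler matching group feature distribution
synth_po_04	synth_po_04	human	PO	GGSGSSSSSSLAAAAAAAAAAAAAAAAAALLQNRQNARNRQRNQQRRRAARA	11	31	synthetic filler matching group feature distribution
synth_po_05	synth_po_05	human	PO	SGSSSSSSSSLLAAAAAAAAAAAAAAAAALLQRQRQNAARNARNRQQNNRQRAARRR	11	31	synthetic filler matching group feature distribution
synth_mito_01	synth_mito_01	human	MITO	GSSSGGSSSSAAAAAAAAAAAAAAAAAAAALQANARAQQANQQN	11	31	synthetic filler matching group feature distribution
synth_mito_02	synth_mito_02	human	MITO	SSSSGSSGSGLAAAAAAAAAAAAAAAAAAALQNAAQAQQRNQN	11	31	synthetic filler matching group feature distribution
synth_mito_03	synth_mito_03	human	MITO	SSSSGSSSSSAAAAAAAAAAGAAAAAAAAAAQANNQANQAQAQRN	11	31	synthetic filler matching group feature distribution
synth_mito_04	synth_mito_04	human	MITO	SSGSSGGGSSLLAAAAAAAAAAAAAAAAAALQQARQNRAR	11	31	synthetic filler matching group feature distribution
synth_mito_05	synth_mito_05	human	MITO	GSGSSGGSGSLLAAAAAAAAAAAAAAAAAALQNNARQQRA	11	31	synthetic filler matching group feature distribution
synth_mito_06	synth_mito_06	human	MITO	GSGSGSSGSGLLAAAAAAAAAAAAAAAAAALQRQNQANQRA	11	31	synthetic filler matching group feature distribution
synth_mito_07	synth_mito_07	human	MITO	SGSGSSGSSSLLAAAAAAAAAAAAAAAALLLQQANNQRA	11	31	synthetic filler matching group feature distribution
synth_mito_08	synth_mito_08	human	MITO	SSGGSSSSGGLAAAAAAAAAAAAAAAAAAALQNQQNAQQANANRRA	11	31	synthetic filler matching group feature distribution
synth_mito_09	synth_mito_09	human	MITO	SSGSGSSSSGAAAAAAAAAAAAAAAAAAAALQAQQNA	11	31	synthetic filler matching group feature distribution
synth_er_01	synth_er_01	human	ER	GGGSGGSSGGLLLAAAAAAAAAAAAAAAALLQRQNQNANQRQAA	11	31	synthetic filler matching group feature distribution
synth_er_02	synth_er_02	human	ER	SGSSGSSGSSLAAAAAAAAAAAAAAAAAAALQNQQARRA	11	31	synthetic filler matching group feature distribution
synth_er_03	synth_er_03	human	ER	GGSSGGSSSSLLLLLLAAAAAAAAALLLLLLQRNQAARQ	11	31	synthetic filler matching group feature distribution
synth_er_04	synth_er_04	human	ER	GGSSGSSSSGLLLLLLLAAAAAAALLLLLLLQQQANNNQAA	11	31	synthetic filler matching group feature distribution
synth_er_05	synth_er_05	human	ER	GSSSSSSSSSLLLLLLAAAAAAAALLLLLLLQRAQRQNNAQ	11	31	synthetic filler matching group feature distribution
synth_er_06	synth_er_06	human	ER	SSSGSSSGSGLLLLLAAAAAAAAAAAALLLLQQAN	11	31	synthetic filler matching group feature distribution
synth_er_07	synth_er_07	human	ER	GGSGSSSSSSLLLLLAAAAAAAAAAAALLLLQAQNQQNAQANA	11	31	synthetic filler matching group feature distribution
synth_er_08	synth_er_08	human	ER	SSSSSSGSGSLLAAAAAAAAAAAAAAAAALLQNQQA	11	31	synthetic filler matching group feature distribution
synth_er_09	synth_er_09	human	ER	SSSGSSSSGSLLLAAAAAAAAAAAAAALLLLQNAAQQ	11	31	synthetic filler matching group feature distribution
synth_er_10	synth_er_10	human	ER	GSSSSSSSSSLAAAAAAAAAAAAAAAAAAALQNAQRQNRQA	11	31	synthetic filler matching group feature distribution
synth_er_11	synth_er_11	human	ER	SSGSSSSGSSLLLAAAAAAAAAAAAAALLLLQAQNQAQAQNNR	11	31	synthetic filler matching group feature distribution
synth_er_12	synth_er_12	human	ER	SSGGSGSGGSLLLAAAAAAAAAAAAAAALLLQQNA	11	31	synthetic filler matching group feature distribution
synth_er_13	synth_er_13	human	ER	SSSGSSSGSGLLLLAAAAAAAAAAAAALLLLQQQNRNQANNAQAA	11	31	synthetic filler matching group feature distribution
synth_er_14	synth_er_14	human	ER	SSSGSSSSSSLLAAAAAAAAAAAAAAAAALLQQNAQAQRN	11	31	synthetic filler matching group feature distribution
synth_er_15	synth_er_15	human	ER	SSSSSSSSSSLLLLLLAAAAAAAAALLLLLLQQNQAAQQNAANN	11	31	synthetic filler matching group feature distribution
synth_er_16	synth_er_16	human	ER	SSGGSGSSSGAAAAAAAAAAAAAAAAAAAALQAQAQRN	11	31	synthetic filler matching group feature distribution
synth_er_17	synth_er_17	human	ER	SGGSSSGSGSLLAAAAAAAAAAAAAAAALLLQNQAQARNQNAR	11	31	synthetic filler matching group feature distribution
synth_er_18	synth_er_18	human	ER	SSSGGSSSSSLLLAAAAAAAAAAAAAALLLLQRNNAQAQ	11	31	synthetic filler matching group feature distribution
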