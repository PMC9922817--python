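# OXPHOS subunit annotation: 98 subunits of complexes CI-CV, of which 13 are
# encoded in the mitochondrial genome (accessions given for those; nuclear
# entries use the gene symbol as protein_id).
# Complex totals are pinned to 45 (CI), 4 (CII), 11 (CIII), 21 (CIV), 17 (CV).
# Module labels follow the published assembly-module nomenclature: CI modules
# N/Q/ND1/ND2/ND4/ND5/NDUFAB1, CIII and CIV subcomplexes, CV assembly steps.
# Entries whose complex membership or module placement is not firmly
# established (isoforms, the UQCRFS1-derived small subunit, NDUFA4) carry
# uncertain=1; an empty module means no module assignment is claimed.
protein_id	gene	encoding	complex	module	uncertain
P03886	MT-ND1	mitochondrial	CI	ND1 module	0
P03891	MT-ND2	mitochondrial	CI	ND2 module	0
P03897	MT-ND3	mitochondrial	CI	ND2 module	0
P03905	MT-ND4	mitochondrial	CI	ND4 module	0
P03901	MT-ND4L	mitochondrial	CI	ND2 module	0
P03915	MT-ND5	mitochondrial	CI	ND5 module	0
P03923	MT-ND6	mitochondrial	CI	ND2 module	0
NDUFV1	NDUFV1	nuclear	CI	N module	0
NDUFV2	NDUFV2	nuclear	CI	N module	0
NDUFV3	NDUFV3	nuclear	CI	N module	0
NDUFS1	NDUFS1	nuclear	CI	N module	0
NDUFS4	NDUFS4	nuclear	CI	N module	0
NDUFS6	NDUFS6	nuclear	CI	N module	0
NDUFA2	NDUFA2	nuclear	CI	N module	0
NDUFA6	NDUFA6	nuclear	CI	N module	0
NDUFA7	NDUFA7	nuclear	CI	N module	0
NDUFA12	NDUFA12	nuclear	CI	N module	0
NDUFS2	NDUFS2	nuclear	CI	Q module	0
NDUFS3	NDUFS3	nuclear	CI	Q module	0
NDUFS7	NDUFS7	nuclear	CI	Q module	0
NDUFS8	NDUFS8	nuclear	CI	Q module	0
NDUFA5	NDUFA5	nuclear	CI	Q module	0
NDUFA3	NDUFA3	nuclear	CI	ND1 module	0
NDUFA8	NDUFA8	nuclear	CI	ND1 module	0
NDUFA13	NDUFA13	nuclear	CI	ND1 module	0
NDUFA9	NDUFA9	nuclear	CI	ND1 module	0
NDUFC1	NDUFC1	nuclear	CI	ND2 module	0
NDUFC2	NDUFC2	nuclear	CI	ND2 module	0
NDUFA1	NDUFA1	nuclear	CI	ND2 module	0
NDUFA10	NDUFA10	nuclear	CI	ND2 module	0
NDUFS5	NDUFS5	nuclear	CI	ND2 module	0
NDUFB1	NDUFB1	nuclear	CI	ND4 module	0
NDUFB4	NDUFB4	nuclear	CI	ND4 module	0
NDUFB5	NDUFB5	nuclear	CI	ND4 module	0
NDUFB6	NDUFB6	nuclear	CI	ND4 module	0
NDUFB10	NDUFB10	nuclear	CI	ND4 module	0
NDUFB11	NDUFB11	nuclear	CI	ND4 module	0
NDUFA11	NDUFA11	nuclear	CI	ND4 module	0
NDUFB2	NDUFB2	nuclear	CI	ND5 module	0
NDUFB3	NDUFB3	nuclear	CI	ND5 module	0
NDUFB7	NDUFB7	nuclear	CI	ND5 module	0
NDUFB8	NDUFB8	nuclear	CI	ND5 module	0
NDUFB9	NDUFB9	nuclear	CI	ND5 module	0
NDUFAB1	NDUFAB1	nuclear	CI	NDUFAB1	0
NDUFA4	NDUFA4	nuclear	CI		1
SDHA	SDHA	nuclear	CII		0
SDHB	SDHB	nuclear	CII		0
SDHC	SDHC	nuclear	CII		0
SDHD	SDHD	nuclear	CII		0
P00156	MT-CYB	mitochondrial	CIII	CIII subcomplex 1	0
UQCRB	UQCRB	nuclear	CIII	CIII subcomplex 1	0
UQCRQ	UQCRQ	nuclear	CIII	CIII subcomplex 1	0
UQCRC1	UQCRC1	nuclear	CIII	CIII subcomplex 2	0
UQCRC2	UQCRC2	nuclear	CIII	CIII subcomplex 2	0
CYC1	CYC1	nuclear	CIII	CIII subcomplex 2	1
UQCRH	UQCRH	nuclear	CIII	CIII subcomplex 2	1
UQCR10	UQCR10	nuclear	CIII	CIII subcomplex 2	1
UQCR11	UQCR11	nuclear	CIII	CIII subcomplex 2	1
UQCRFS1	UQCRFS1	nuclear	CIII	CIII subcomplex 3	0
UQCRFS1-SU9	UQCRFS1	nuclear	CIII	CIII subcomplex 3	1
P00395	MT-CO1	mitochondrial	CIV	CIV subcomplex 2	0
P00403	MT-CO2	mitochondrial	CIV	CIV subcomplex 2	0
P00414	MT-CO3	mitochondrial	CIV	CIV subcomplex 2	0
COX4I1	COX4I1	nuclear	CIV	CIV subcomplex 1	0
COX5A	COX5A	nuclear	CIV	CIV subcomplex 1	0
COX4I2	COX4I2	nuclear	CIV	CIV subcomplex 1	1
COX5B	COX5B	nuclear	CIV	CIV subcomplex 2	0
COX6C	COX6C	nuclear	CIV	CIV subcomplex 2	0
COX7C	COX7C	nuclear	CIV	CIV subcomplex 2	0
COX8A	COX8A	nuclear	CIV	CIV subcomplex 2	0
COX6A1	COX6A1	nuclear	CIV		0
COX6B1	COX6B1	nuclear	CIV		0
COX7A2	COX7A2	nuclear	CIV		0
COX7B	COX7B	nuclear	CIV		0
COX6A2	COX6A2	nuclear	CIV		1
COX6B2	COX6B2	nuclear	CIV		1
COX7A1	COX7A1	nuclear	CIV		1
COX7A2L	COX7A2L	nuclear	CIV		1
COX7B2	COX7B2	nuclear	CIV		1
COX8C	COX8C	nuclear	CIV		1
COX8B	COX8B	nuclear	CIV		1
P00846	MT-ATP6	mitochondrial	CV	CV step 3	0
P03928	MT-ATP8	mitochondrial	CV	CV step 3	0
ATP5F1A	ATP5F1A	nuclear	CV	CV step 1	0
ATP5F1B	ATP5F1B	nuclear	CV	CV step 1	0
ATP5F1C	ATP5F1C	nuclear	CV	CV step 1	0
ATP5F1D	ATP5F1D	nuclear	CV	CV step 1	0
ATP5F1E	ATP5F1E	nuclear	CV	CV step 1	0
ATP5MC1	ATP5MC1	nuclear	CV	CV step 1	1
ATP5MC2	ATP5MC2	nuclear	CV	CV step 1	1
ATP5MC3	ATP5MC3	nuclear	CV	CV step 1	1
ATP5PB	ATP5PB	nuclear	CV	CV step 2	0
ATP5PD	ATP5PD	nuclear	CV	CV step 2	0
ATP5PF	ATP5PF	nuclear	CV	CV step 2	0
ATP5PO	ATP5PO	nuclear	CV	CV step 2	0
ATP5ME	ATP5ME	nuclear	CV	CV step 3	0
ATP5MF	ATP5MF	nuclear	CV	CV step 3	0
ATP5MG	ATP5MG	nuclear	CV	CV step 3	0
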