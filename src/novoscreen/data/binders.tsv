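binder_id	target_receptor	receptor_family	chain_class	length_aa	kd_nM	origin	blocks_native_site
b_41BB	41BB	tnf_family	non_cytokine	56	NA	prior_work	false
b_ALK1	ALK1	growth_factor	non_cytokine	56	NA	prior_work	false
b_ActRII	ActRII	growth_factor	non_cytokine	58	NA	prior_work	false
b_BMPR2	BMPR2	growth_factor	non_cytokine	59	NA	prior_work	false
b_CTLA4	CTLA4	checkpoint	non_cytokine	60	NA	prior_work	false
b_EGFR	EGFR	growth_factor	non_cytokine	61	NA	prior_work	false
b_FGFR	FGFR	growth_factor	non_cytokine	63	NA	prior_work	false
b_HER2	HER2	growth_factor	non_cytokine	65	NA	prior_work	false
b_IFNAR1	IFNAR1	cytokine_private	private	64	10.3	rosetta	true
b_IFNAR2	IFNAR2	cytokine_private	private	78	180.4	rfdiffusion	false
b_IFNLR	IFNLR	cytokine_private	private	59	NA	prior_work	true
b_IGF1R	IGF1R	growth_factor	non_cytokine	66	NA	prior_work	false
b_IL10Ra	IL10Ra	cytokine_private	private	58	NA	prior_work	true
b_IL10Rb	IL10Rb	cytokine_common	common	82	149.7	rfdiffusion	false
b_IL12Rb1	IL12Rb1	cytokine_private	private	99	5.9	rosetta	false
b_IL17Ra	IL17Ra	cytokine_private	private	65	NA	prior_work	true
b_IL21Ra	IL21Ra	cytokine_private	private	57	NA	prior_work	true
b_IL23Ra	IL23Ra	cytokine_private	private	63	NA	prior_work	true
b_IL2Rb	IL2Rb	cytokine_private	private	100	177.1	redesigned_agonist	true
b_IL4Ra	IL4Ra	cytokine_private	private	129	88	redesigned_agonist	true
b_IL7Ra	IL7Ra	cytokine_private	private	60	NA	prior_work	true
b_INSR	INSR	growth_factor	non_cytokine	67	NA	prior_work	false
b_OX40	OX40	tnf_family	non_cytokine	55	NA	prior_work	false
b_PDL1	PDL1	checkpoint	non_cytokine	62	NA	prior_work	false
b_TGFbR2	TGFbR2	growth_factor	non_cytokine	60	NA	prior_work	false
b_TNFR1	TNFR1	tnf_family	non_cytokine	58	NA	prior_work	false
b_TNFR2	TNFR2	tnf_family	non_cytokine	57	NA	prior_work	false
b_TSLPR	TSLPR	cytokine_private	private	61	179.8	rosetta	true
b_TrkA	TrkA	growth_factor	non_cytokine	62	NA	prior_work	false
b_betac	betac	cytokine_common	common	58	80.7	rosetta	true
b_cKit	cKit	growth_factor	non_cytokine	64	NA	prior_work	false
b_gammac	gammac	cytokine_common	common	62	20.4	rosetta	true
b_gp130	gp130	cytokine_common	common	61	NA	prior_work	true
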