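region	hemisphere	lobe
L_OFCl	L	OFC
L_OFCm	L	OFC
L_OFCc	L	OFC
L_PFCdl	L	PFC
L_PFCdm	L	PFC
L_PFCvl	L	PFC
L_PFCm	L	PFC
L_PFCcl	L	PFC
L_PFCpol	L	PFC
L_FEF	L	PFC
L_CCa	L	cingulate
L_CCp	L	cingulate
L_CCr	L	cingulate
L_CCs	L	cingulate
L_M1	L	motor_somatosensory
L_PMCdl	L	motor_somatosensory
L_PMCm	L	motor_somatosensory
L_PMCvl	L	motor_somatosensory
L_S1	L	motor_somatosensory
L_S2	L	motor_somatosensory
L_IP	L	parietal
L_PCi	L	parietal
L_PCip	L	parietal
L_PCm	L	parietal
L_PCs	L	parietal
L_PCun	L	parietal
L_A1	L	temporal
L_A2	L	temporal
L_TCc	L	temporal
L_TCi	L	temporal
L_TCpol	L	temporal
L_TCs	L	temporal
L_TCv	L	temporal
L_PHC	L	temporal
L_STP	L	temporal
L_V1	L	occipital
L_V2	L	occipital
L_VACd	L	occipital
L_VACv	L	occipital
L_Ia	L	insula
L_Ip	L	insula
L_Thal	L	subcortical
L_Put	L	subcortical
L_GP	L	subcortical
L_Cd	L	subcortical
L_Hipp	L	subcortical
L_Amyg	L	subcortical
R_OFCl	R	OFC
R_OFCm	R	OFC
R_OFCc	R	OFC
R_PFCdl	R	PFC
R_PFCdm	R	PFC
R_PFCvl	R	PFC
R_PFCm	R	PFC
R_PFCcl	R	PFC
R_PFCpol	R	PFC
R_FEF	R	PFC
R_CCa	R	cingulate
R_CCp	R	cingulate
R_CCr	R	cingulate
R_CCs	R	cingulate
R_M1	R	motor_somatosensory
R_PMCdl	R	motor_somatosensory
R_PMCm	R	motor_somatosensory
R_PMCvl	R	motor_somatosensory
R_S1	R	motor_somatosensory
R_S2	R	motor_somatosensory
R_IP	R	parietal
R_PCi	R	parietal
R_PCip	R	parietal
R_PCm	R	parietal
R_PCs	R	parietal
R_PCun	R	parietal
R_A1	R	temporal
R_A2	R	temporal
R_TCc	R	temporal
R_TCi	R	temporal
R_TCpol	R	temporal
R_TCs	R	temporal
R_TCv	R	temporal
R_PHC	R	temporal
R_STP	R	temporal
R_V1	R	occipital
R_V2	R	occipital
R_VACd	R	occipital
R_VACv	R	occipital
R_Ia	R	insula
R_Ip	R	insula
R_Thal	R	subcortical
R_Put	R	subcortical
R_GP	R	subcortical
R_Cd	R	subcortical
R_Hipp	R	subcortical
R_Amyg	R	subcortical
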