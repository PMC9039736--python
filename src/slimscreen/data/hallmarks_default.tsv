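# Ten cancer hallmarks -> pertinent Reactome pathway ids.
Avoiding immune destruction	R-HSA-168256.7
Enabling replicative immortality	R-HSA-157579.5
Tumor-promoting inflammation	R-HSA-388841.4
Tumor-promoting inflammation	R-HSA-622312.1
Tumor-promoting inflammation	R-HSA-1280215.5
Activating invasion & metastasis	R-HSA-6806834.2
Activating invasion & metastasis	R-HSA-3304351.2
Activating invasion & metastasis	R-HSA-2173791.1
Activating invasion & metastasis	R-HSA-9013694.2
Activating invasion & metastasis	R-HSA-9012852.2
Inducing angiogenesis	R-HSA-194138.2
Genome instability & mutation	R-HSA-73894.3
Resisting cell death	R-HSA-5357801.2
Deregulating cellular energetics	R-HSA-1430728.10
Sustaining proliferative signaling	R-HSA-177929.2
Evading growth suppressors	R-HSA-69278.4
Evading growth suppressors	R-HSA-9675126.2
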