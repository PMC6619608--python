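sample_code	region	site	latitude	longitude	vegetation_zone	species_range	accession
EH103	Taymyr	TY02	72.54861	105.74611	single-tree stands	L. gmelinii	MK468646
EH90	Taymyr	TY02	72.54896	105.74469	single-tree stands	L. gmelinii	MK468638
EH91	Taymyr	TY02	72.54865	105.74546	single-tree stands	L. gmelinii	MK468639
EH80	Taymyr	TY04	72.40889	105.44795	forest line	L. gmelinii	MK468633
EH83	Taymyr	TY04	72.40880	105.44791	forest line	L. gmelinii	MK468634
EH105	Taymyr	TY04	72.40881	105.44818	forest line	L. gmelinii	MK468648
EH84	Taymyr	TY09	72.14373	102.0624	forest line	L. gmelinii	MK468635
EH85	Taymyr	TY09	72.14367	102.06234	forest line	L. gmelinii	MK468636
EH86	Taymyr	TY09	72.14372	102.06265	forest line	L. gmelinii	MK468637
EH77	Taymyr	CH06	70.66506	97.70614	dense forest	L. gmelinii	MK468630
EH78	Taymyr	CH06	70.66496	97.70624	dense forest	L. gmelinii	MK468631
EH79	Taymyr	CH06	70.66485	97.70609	dense forest	L. gmelinii	MK468632
EH104	Omoloy	OMV1	70.74418	132.69852	forest line	L. cajanderi	MK468647
EH96	Omoloy	OMV2	70.72644	132.65817	forest line	L. cajanderi	MK468643
EH97	Omoloy	OMV4	70.52671	132.91426	dense forest	L. cajanderi	MK468644
EH98	Omoloy	OMH3	70.34396	132.90079	dense forest	L. cajanderi	MK468645
EH94	Kolyma	KO05	69.11839	161.02343	single trees on polygonal ridges	L. cajanderi	MK468642
EH92	Kolyma	KO04	69.05129	161.2066	open forest	L. cajanderi	MK468640
EH93	Kolyma	KO02	68.38994	161.449	dense forest	L. cajanderi	MK468641
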