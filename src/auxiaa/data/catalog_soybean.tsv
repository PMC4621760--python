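gene_id	chromosome	cluster_id	canonical_status	mode	pair_partner	expression_class
GmIAA1	chr1		canonical	wgd_segmental	GmIAA30	conserved
GmIAA2	chr1		canonical	wgd_segmental	GmIAA12	
GmIAA3	chr1		canonical	wgd_segmental	GmIAA28	conserved
GmIAA4	chr2		canonical	transposed		
GmIAA5	chr2		non_canonical	wgd_segmental	GmIAA35	
GmIAA6	chr2	SC1	non_canonical	tandem	GmIAA33	conserved
GmIAA7	chr2	SC1	canonical	tandem		
GmIAA8	chr2	SC1	canonical	wgd_segmental	GmIAA32	conserved
GmIAA9	chr2		canonical	wgd_segmental	GmIAA48	conserved
GmIAA10	chr3	SC2	canonical	wgd_segmental	GmIAA55	diverged
GmIAA11	chr3	SC2	canonical	wgd_segmental	GmIAA56	conserved
GmIAA12	chr3		canonical	wgd_segmental	GmIAA2	
GmIAA13	chr3		non_canonical	wgd_segmental	GmIAA58	conserved
GmIAA14	chr3		canonical	wgd_segmental	GmIAA59	diverged
GmIAA15	chr4		canonical	wgd_segmental	GmIAA18	diverged
GmIAA16	chr4		canonical	wgd_segmental	GmIAA19	diverged
GmIAA17	chr5		canonical	wgd_segmental	GmIAA24	conserved
GmIAA18	chr6		canonical	wgd_segmental	GmIAA15	diverged
GmIAA19	chr6		canonical	wgd_segmental	GmIAA16	diverged
GmIAA20	chr7		canonical	wgd_segmental	GmIAA23	
GmIAA21	chr7		canonical	wgd_segmental	GmIAA26	diverged
GmIAA22	chr7		canonical	wgd_segmental	GmIAA27	diverged
GmIAA23	chr7		non_canonical	wgd_segmental	GmIAA20	
GmIAA24	chr8		canonical	wgd_segmental	GmIAA17	conserved
GmIAA25	chr8		canonical	wgd_segmental	GmIAA29	
GmIAA26	chr8		canonical	wgd_segmental	GmIAA21	diverged
GmIAA27	chr8		canonical	wgd_segmental	GmIAA22	diverged
GmIAA28	chr8		canonical	wgd_segmental	GmIAA3	conserved
GmIAA29	chr9		canonical	wgd_segmental	GmIAA25	
GmIAA30	chr9		canonical	wgd_segmental	GmIAA1	conserved
GmIAA31	chr10		non_canonical	transposed		
GmIAA32	chr10	SC3	canonical	wgd_segmental	GmIAA8	conserved
GmIAA33	chr10	SC3	canonical	wgd_segmental	GmIAA6	conserved
GmIAA34	chr10		canonical	wgd_segmental	GmIAA41	conserved
GmIAA35	chr10		non_canonical	wgd_segmental	GmIAA5	
GmIAA36	chr10		canonical	wgd_segmental	GmIAA63	conserved
GmIAA37	chr10	SC4	non_canonical	wgd_segmental	GmIAA62	conserved
GmIAA38	chr10	SC4	canonical	wgd_segmental	GmIAA61	conserved
GmIAA39	chr10		non_canonical	wgd_segmental	GmIAA60	diverged
GmIAA40	chr13		non_canonical	wgd_segmental	GmIAA53	conserved
GmIAA41	chr13		canonical	wgd_segmental	GmIAA34	conserved
GmIAA42	chr13		non_canonical	transposed		
GmIAA43	chr13		canonical	wgd_segmental	GmIAA54	conserved
GmIAA44	chr13		canonical	wgd_segmental	GmIAA52	conserved
GmIAA45	chr13		canonical	wgd_segmental	GmIAA51	conserved
GmIAA46	chr13	SC5	canonical	wgd_segmental	GmIAA50	diverged
GmIAA47	chr13	SC5	canonical	wgd_segmental	GmIAA49	
GmIAA48	chr14		canonical	wgd_segmental	GmIAA9	conserved
GmIAA49	chr15	SC6	canonical	wgd_segmental	GmIAA47	
GmIAA50	chr15	SC6	canonical	wgd_segmental	GmIAA46	diverged
GmIAA51	chr15		canonical	wgd_segmental	GmIAA45	conserved
GmIAA52	chr15		canonical	wgd_segmental	GmIAA44	conserved
GmIAA53	chr17		non_canonical	wgd_segmental	GmIAA40	conserved
GmIAA54	chr17		canonical	wgd_segmental	GmIAA43	conserved
GmIAA55	chr19	SC7	canonical	wgd_segmental	GmIAA10	diverged
GmIAA56	chr19	SC7	canonical	wgd_segmental	GmIAA11	conserved
GmIAA57	chr19		canonical	dispersed		
GmIAA58	chr19		non_canonical	wgd_segmental	GmIAA13	conserved
GmIAA59	chr19		canonical	wgd_segmental	GmIAA14	diverged
GmIAA60	chr20		non_canonical	wgd_segmental	GmIAA39	diverged
GmIAA61	chr20	SC8	canonical	wgd_segmental	GmIAA38	conserved
GmIAA62	chr20	SC8	canonical	wgd_segmental	GmIAA37	conserved
GmIAA63	chr20		canonical	wgd_segmental	GmIAA36	conserved
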