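gene_id	chromosome	cluster_id	canonical_status	mode	pair_partner	expression_class
CaIAA1	chr1		canonical	dispersed		
CaIAA2	chr2		canonical	dispersed		
CaIAA3	chr3	SC1	canonical	tandem		
CaIAA4	chr3	SC1	canonical	tandem		
CaIAA5	chr3		non_canonical	dispersed		
CaIAA6	chr4		canonical	dispersed		
CaIAA7	chr4		canonical	dispersed		
CaIAA8	chr4		canonical	dispersed		
CaIAA9	chr4		canonical	dispersed		
CaIAA10	chr4		canonical	dispersed		
CaIAA11	chr4		non_canonical	dispersed		
CaIAA12	chr4		non_canonical	dispersed		
CaIAA13	chr4		canonical	dispersed		
CaIAA14	chr5		canonical	dispersed		
CaIAA15	chr6		canonical	dispersed		
CaIAA16	chr6		non_canonical	dispersed		
CaIAA17	chr7		non_canonical	dispersed		
CaIAA18	chr7		canonical	dispersed		
CaIAA19	chr7		non_canonical	dispersed		
CaIAA20	chr7		canonical	dispersed		
CaIAA21	chr7		canonical	dispersed		
CaIAA22	chr8		canonical	dispersed		
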