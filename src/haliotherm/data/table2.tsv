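gene_id	pathways	log2fc_RL	log2fc_YL	description
c68273_g1	Cell cycle	-5.7	-4.8	Cyclin A
c76770_g1	Cell cycle	-2.2		Polo-like kinase 1
c79314_g1	Cell cycle	-1.9		Anaphase-promoting complex subunit 12
c81134_g1	DNA replication	-2.2		Ribonuclease H2 subunit C
c86856_g2	DNA replication, cell cycle	-2.0		DNA replication licensing factor MCM6
c86983_g1	Cell cycle	-2.6	-2.5	Cyclin B
c88219_g1	DNA replication, cell cycle		-2.9	DNA replication licensing factor MCM3
c91413_g2	DNA replication	-1.8		Replication factor A2
c91496_g1	DNA replication, cell cycle	-1.8		DNA replication licensing factor MCM2
c93600_g1	DNA replication, cell cycle	-3.0	-2.9	DNA replication licensing factor MCM7
c94298_g1	DNA replication, cell cycle	-2.5		DNA replication licensing factor MCM5
c94298_g2	DNA replication, cell cycle	-3.1	-3.9	DNA replication licensing factor MCM5
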