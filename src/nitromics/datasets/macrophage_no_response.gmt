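ETC_Complex_I	NADH:ubiquinone oxidoreductase structural subunits	Ndufa1	Ndufa2	Ndufa3	Ndufa4	Ndufa5	Ndufa6	Ndufa7	Ndufa8	Ndufa9	Ndufa10	Ndufa11	Ndufa12	Ndufa13	Ndufab1	Ndufb2	Ndufb3	Ndufb4	Ndufb5	Ndufb6	Ndufb7	Ndufb8	Ndufb9	Ndufb10	Ndufb11	Ndufc1	Ndufc2	Ndufs1	Ndufs2	Ndufs3	Ndufs4	Ndufs5	Ndufs6	Ndufs7	Ndufs8	Ndufv1	Ndufv2	Ndufv3
ETC_Complex_II	Succinate dehydrogenase subunits	Sdha	Sdhb	Sdhc	Sdhd
ETC_Complex_III	Ubiquinol-cytochrome c reductase subunits	Uqcrc1	Uqcrc2	Uqcrfs1	Cyc1	Uqcrb	Uqcrq	Uqcrh	Uqcr10	Uqcr11
ETC_Complex_IV	Cytochrome c oxidase structural subunits	Cox4i1	Cox4i2	Cox5a	Cox5b	Cox6a1	Cox6a2	Cox6b1	Cox6b2	Cox6c	Cox7a1	Cox7a2	Cox7a2l	Cox7b	Cox7c	Cox8a	Cox8b
ETC_Complex_V	Mitochondrial F-type ATP synthase subunits	Atp5a1	Atp5b	Atp5c1	Atp5d	Atp5e	Atp5f1	Atp5g1	Atp5g2	Atp5g3	Atp5h	Atp5j	Atp5j2	Atp5k	Atp5l	Atp5o	Atpif1
COX_assembly_chaperones	Cytochrome c oxidase assembly factors, analyzed apart from Complex IV structural subunits	Cox10	Cox11	Cox15	Cox17	Cox19	Cox20
Mitochondrially_encoded	The 13 mtDNA-encoded OXPHOS subunits	mt-Nd1	mt-Nd2	mt-Nd3	mt-Nd4	mt-Nd4l	mt-Nd5	mt-Nd6	mt-Cytb	mt-Co1	mt-Co2	mt-Co3	mt-Atp6	mt-Atp8
V_ATPase	Vacuolar H+-ATPase subunits, distinct from mitochondrial ATP synthase	Atp6v0a1	Atp6v0b	Atp6v0c	Atp6v0d1	Atp6v0d2	Atp6v0e	Atp6v1a	Atp6v1b2	Atp6v1c1	Atp6v1d	Atp6v1e1	Atp6v1f	Atp6v1g1	Atp6v1h
Denitrosylases	Curated denitrosylation and low-molecular-weight thiol reduction enzymes	Ahd5	Txn1	Txn2	Txnrd1	Txnrd2	Grx1	Grx2	Grx3	Grx5	Glrx	Glrx2	Trp14	Txndc17	Apex1	Prdx1	Prdx2	Akr1a1
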