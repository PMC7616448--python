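# Synthetic stand-in panel of 103 mouse immediate-early / activity-regulated
# genes curated for this package from the canonical IEG literature (AP-1 and
# Egr families, Nr4a orphan receptors, Npas4, Arc/Homer1 synaptic IEGs,
# Dusp phosphatases and other rapid primary-response transcripts).
Arc
Fos
Fosb
Fosl1
Fosl2
Jun
Junb
Jund
Egr1
Egr2
Egr3
Egr4
Npas4
Nr4a1
Nr4a2
Nr4a3
Homer1
Bdnf
Dusp1
Dusp2
Dusp4
Dusp5
Dusp6
Dusp14
Ier2
Ier3
Ier5
Ier5l
Btg1
Btg2
Gadd45a
Gadd45b
Gadd45g
Atf3
Maff
Mafk
Klf2
Klf4
Klf6
Klf10
Per1
Per2
Sik1
Trib1
Rgs2
Rgs4
Plk2
Ptgs2
Tiparp
Pcsk1
Scg2
Vgf
Nptx2
Pim1
Pim3
Cebpb
Cebpd
Crem
Srf
Nfkbia
Nfkbiz
Socs3
Errfi1
Zfp36
Zfp36l1
Zfp36l2
Csrnp1
Ppp1r15a
Sgk1
Slc2a3
Sertad1
Midn
Gpr3
Inhba
Bhlhe40
Bhlhe41
Coq10b
Fbxo33
Spry2
Spry4
Rasd1
Rasl11a
Kdm6b
Baz1a
Arl4d
Arl5b
Ccn1
Ccn2
Dnajb5
Nrn1
Pcdh8
Adamts1
Nfil3
Irs2
Cdkn1a
Penk
Crh
Rheb
Gem
Nab2
Rrad
Apold1
Dnajb1
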