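protein,abbreviation,category,reported_fold,reported_p
Mucin 6,MUC6,ecm,-4.2,0.01
Fibulin-1,FBLN1,ecm,-1.3,<0.01
Laminin alpha 4,LAMA4,ecm,-1.2,0.02
Laminin gamma 1,LAMC1,ecm,-1.1,0.07
Syndecan 2,SDC2,ecm,1.3,0.01
Plasminogen activator 1,PAI-1,ecm,1.1,0.10
Tenascin C,TNC,ecm,-1.3,0.01
Collagen 1 alpha 2,COL1A2,ecm,-1.2,0.08
VE-Cadherin,VE-Cad,cell_type_marker,1.1,0.10
Angiopoietin 2,ANG-2,cell_type_marker,-1.2,0.04
Vitronectin,VTN,cell_type_marker,1.4,<0.01
Myosin-11,MYH-11,cell_type_marker,1.5,0.04
Calponin 3,CNN3,cell_type_marker,-1.2,0.04
YAP1,YAP1,emt_regulator,1.2,0.06
Vascular endothelial growth factor receptor,VEGFr,emt_regulator,-1.3,0.03
Alpha actinin 4,ACTN4,emt_regulator,1.2,0.04
Integrin alpha 5,ITGA5,emt_regulator,-1.2,0.03
Integrin beta 3,ITGB3,emt_regulator,-1.2,0.06
Migration and invasion enhancer 1,MIEN1,other_emt,1.6,<0.01
Osteoclast stimulating factor 1,OSTF1,other_emt,1.3,0.01
Sirtuin 2,SIRT2,other_emt,1.3,<0.01
Aldehyde dehydrogenase 1 family member A3,ALDH1A3,other_emt,1.3,0.01
Thioredoxin,TXN,other_emt,1.3,0.09
Rho GDP-dissociation inhibitor 2,RhoGDI2,other_emt,1.2,0.05
Signal transducer and activator of transcription 3,STAT3,other_emt,1.2,0.03
Serine/threonine kinase receptor associated protein,STRAP,other_emt,1.1,0.06
Myocyte enhancer factor-2,MEF2,other_emt,-1.7,0.01
Receptor tyrosine kinase-like orphan receptor 1,ROR1,other_emt,-1.2,0.03
Ras-related C3 botulinum toxin substrate 1,RAC1,other_emt,1.1,0.06
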