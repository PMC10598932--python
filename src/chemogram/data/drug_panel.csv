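drug,class,log10M_low,log10M_medium,log10M_high,solvent
5FU,chemotherapy,-7,-6.25,-5.5,DMSO
Azacitidine,epigenetic,-6.5,-5.75,-5,DMSO
Bortesomib,other,-9.25,-8.5,-7.75,DMSO
Carboplatin,chemotherapy,-6.25,-5.5,-4.75,PBS_tween
Cobimetinib,kinase_inhibitor,-8,-7.25,-6.5,DMSO
Docetaxel,chemotherapy,-9.25,-8.75,-8.25,DMSO
Doxorubicin,chemotherapy,-8,-7.25,-6.5,DMSO
Etoposide,chemotherapy,-6.75,-6,-5.25,DMSO
Everolimus,kinase_inhibitor,-8.5,-7.75,-7,DMSO
Fludarabine,chemotherapy,-8,-7.25,-6.5,DMSO
Gefetinib,kinase_inhibitor,-7.5,-6.75,-6,DMSO
Gemcitabine,chemotherapy,-7.5,-6.75,-6,DMSO
Lapatinib,kinase_inhibitor,-7,-6.25,-5.5,DMSO
Mitomycin,chemotherapy,-8,-7.25,-6.5,DMSO
Olaparib,other,-6.5,-5.75,-5,DMSO
Oxaliplatin,chemotherapy,-6.5,-5.75,-5,PBS_tween
Paclitaxel,chemotherapy,-9,-8.5,-8,DMSO
Pemetrexed,chemotherapy,-8.25,-7.5,-6.75,DMSO
Raltitrexed,chemotherapy,-9,-8.5,-8,DMSO
Regorafenib,kinase_inhibitor,-6.5,-5.75,-5,DMSO
SN-38,chemotherapy,-9,-8.5,-8,DMSO
Sunitinib,kinase_inhibitor,-7,-6.5,-6,DMSO
Trifluridin-tipiracil,chemotherapy,-6.5,-5.75,-5,PBS_tween
Vinorelbine,chemotherapy,-8.75,-8,-7.25,DMSO
Vorinostat,epigenetic,-6.75,-6.25,-5.75,DMSO
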