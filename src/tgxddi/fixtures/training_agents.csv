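agent,class,pa,c2dc,pca,overall,cd,ames,solvent,dose_range,array_conc
Cisplatin,Alkylating agents,,,,,,,0.9% NaCl,10 ~ 80 uM,80 uM
Methyl methane sulfonate (MMS),Alkylating agents,,,,,,,H2O,20 ~ 200 ug/ml,100 ug/ml
Camptothecin,Topoisomerase I inhibitors,,,,,,,DMSO,62.5 ~ 500 nM,125 nM
Etoposide,Topoisomerase II inhibitors,,,,,,,DMSO,50 ~ 400 nM,200 nM
5-fluorouracil (5-FU),RNA/DNA antimetabolites,,,,,,,DMSO,6.25 ~ 50 ug/ml,25 ug/ml
Methotrexate,RNA/DNA antimetabolites,,,,,,,DMSO,0.05 ~ 1 mM,100 uM
Arabinofuranosyl cytidine (AraC),DNA antimetabolites,,,,,,,H2O,12.5 ~ 50 uM,50 uM
Hydroxyurea,DNA antimetabolites,,,,,,,H2O,0.25 ~ 1 mM,0.5 mM
Gamma-rays,Causing DNA strand break by other mechanisms,,,,,,,N/A,4 Gy,4 Gy
Bleomycin,Causing DNA strand break by other mechanisms,,,,,,,H2O,5 ~ 40 ug/ml,10 ug/ml
Hydrogen peroxide,Causing DNA strand break by other mechanisms,,,,,,,N/A,20 ~ 80 uM,80 uM
Colchicine,Antimitotic agents,,,,,,,Ethanol,62.5 ~ 1000 ng/ml,250 ng/ml
Docetaxel,Antimitotic agents,,,,,,,DMSO,25 ~ 100 nM,50 nM
Paclitaxel,Antimitotic agents,,,,,,,DMSO,12.5 ~ 200 nM,50 nM
Vinblastin,Antimitotic agents,,,,,,,DMSO,50 ~ 800 ng/ml,200 ng/ml
Trichostatin A (TSA),Histone modification inhibitors,,,,,,,DMSO,5 ~ 80 ng/ml,20 ng/ml
Apicidin,Histone modification inhibitors,,,,,,,DMSO,0.25 ~ 4 ug/ml,1 ug/ml
HC toxin,Histone modification inhibitors,,,,,,,Methanol,5 ~ 80 ng/ml,20 ng/ml
Oxamflatin,Histone modification inhibitors,,,,,,,DMSO,0.25 ~ 4 uM,1 uM
Tunicamysin,Endoplasmic reticulum modulator,,,,,,,Methanol,1.25 ~ 10 ug/ml,2.5 ug/ml
Thapsigargin,Endoplasmic reticulum modulator,,,,,,,Ethanol,62.5 ~ 500 nM,250 nM
2-deoxy-D-glucose (2-DG),Glycolysis inhibitor,,,,,,,H2O,0.16 ~ 20 uM,20 uM
Antimycin A,Energy metabolism inhibitor (uncoupling agent),,,,,,,Ethanol,25 ~ 200 uM,100 uM
Cadmium chloride,Heavy metals,,,,,,,H2O,50 ~ 800 uM,50 uM
Potassium chromate (VI),Heavy metals,,,,,,,H2O,25 ~ 400 uM,100 uM
Sodium arsenite,Heavy metals,,,,,,,H2O,10 ~ 90 uM,30 uM
Heat shock,Other stresses,,,,,,,N/A,47C,47C
Ethanol,Other stresses,,,,,,,N/A,"2%, 4%","2%, 4%"
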