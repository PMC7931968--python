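agent,class,pa,c2dc,pca,overall,cd,ames
N-Ethyl-N-Nitrosourea (ENU),1,+,+,+,+,+,+
Mitomycin (MMC),1,+,+,+,+,+,+
Ethyl methanesulfonate (EMS),1,+,+,+,+,+,+
Belomycin,1,+,+,+,+,+,+
Nitrogen mustard,1,+,+,+,+,+,+
Chlorambucil,1,+,+,+,+,+,+
Busulfan,1,-,+,-,+,+,+
Isopropyl methanesulfonate,1,+,+,+,+,+,+
Hydroquinone,1,-,+,+/-,+,+,+
Doxorubicin,2A,+,+,+,+,+,+
Genistein,2A,+,+,+,+,+,-
Topotecan,2A,+,+,+,+,+,+
Norfloxacin,2A,-,-,-,-,+,-
Ciprofloxacin,2A,+/-,+,+,+,+,-
5-Fluorouracil (5-FU),2B,+,+,+,+,+,+
Thioguanine (6-TG),2B,+,+,+,+,+,-
Thiopurine (6-MP),2B,-,-,-,-,+,-
Azidothymidine (AZT),2B,-,-,-,-,+,-
5-azacytidine (5-AzaC),2B,-,-,-,-,+,+
Dasatinib,3A,+,+,+,+,+,-
Imatinib mesylate,3A,-,-,-,-,+,-
Sorafenib,3A,-,-,-,-,+,-
Benomyl,3B,-,-,-,-,+,-
Diethylstilbestrol,3B,-,+,+,+,+,-
Nocodazole,3B,-,-,-,-,+,-
Sunitinib maleate,4A,-,-,-,-,-,-
Gefinitib,4A,-,-,-,-,-,-
Progesterone,4A,-,-,-,-,-,-
Diethanolamine,4A,-,-,-,-,-,-
Melamine,4A,-,-,-,-,-,-
Ampicillin,4C,-,-,-,-,-,-
Erythromycin Stearate,4C,-,-,-,-,-,-
D-Mannitol,4D,-,-,-,-,-,-
n-Butyl Chloride,4D,-,-,-,-,-,-
3-Nitropropionic acid,4D,-,-,-,-,-,-
Methyl Carbamate,4D,+,+/-,+,+,-,-
Phenobarbital,5,-,-,-,-,+,-
Esomeprazole,5,-,-,-,-,+,-
Donepezil,5,-,-,-,-,+,-
Cyclohexamide,5,-,-,-,-,+,-
"2,4 Dinitrophenol (2,4 DNP)",5,-,-,-,-,+,-
Olmesartan,5,-,-,-,-,+,-
Exemastan,5,+,+,+,+,+,-
Rabeprazole-NA,5,-,-,-,-,+,-
Rotigotin,5,-,-,-,-,+,-
Dexamethasone,5,-,-,-,-,+,-
Caffeine,5,-,-,-,-,+,-
Staurosporine,5,-,-,-,-,+,-
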