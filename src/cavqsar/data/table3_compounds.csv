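name,pubchem_cid,structure_record,split,subclass,hydroxyl_positions,methoxy_positions,other_substituents
"5,7,2'-Trihydroxyflavone",21611827,Structure2D_CID_21611827,train,Flavone,"5,7,2'",,
"Naringin",442428,Structure2D_CID_442428,train,Flavanone,"5,4'",,O-beta-Neo-hesperidose
"(±)-Taxifolin",471,Structure2D_CID_471,train,Flavanone,"3,5,7,3',4'",,
"Quercetin",5280343,Structure2D_CID_5280343,train,Flavonol,"3,5,7,3',4'",,
"Apigenin",5280443,Structure2D_CID_5280443,train,Flavone,"5,7,4'",,
"Luteolin",5280445,Structure2D_CID_5280445,train,Flavone,"5,7,3',4'",,
"Rutin",5280805,Structure2D_CID_5280805,train,Flavonol,"5,7,3',4'",,O-Rutinose
"Kaempferol",5280863,Structure2D_CID_5280863,train,Flavonol,"3,5,7,4'",,
"Genistein",5280961,Structure2D_CID_5280961,train,Flavonol,"5,7,4'",,
"Baicalein",5281605,Structure2D_CID_5281605,train,Flavone,"5,6,7",,
"Chrysin",5281607,Structure2D_CID_5281607,train,Flavone,"5,7",,
"Resokaempferol",5281611,Structure2D_CID_5281611,train,Flavonol,"3,7,4'",,
"Galangin",5281616,Structure2D_CID_5281616,train,Flavonol,"3,5,7",,
"Isorhamnetin",5281654,Structure2D_CID_5281654,train,Flavonol,"3,5,7,4'",3',
"Morin",5281670,Structure2D_CID_5281670,train,Flavonol,"3,5,7,2',4'",,
"Myricetin",5281672,Structure2D_CID_5281672,train,Flavonol,"3,5,7,3',4',5'",,
"Scutellarein",5281697,Structure2D_CID_5281697,train,Flavone,"5,6,7,4'",,
"Tamarixetin",5281699,Structure2D_CID_5281699,train,Flavonol,"3,5,7,3'",4',
"Daidzein",5281708,Structure2D_CID_5281708,train,Isoflavone,"7,4'",,
"3-Methyl galangin",5281946,Structure2D_CID_5281946,train,Flavonol,"5,7",3,
"5-Hydroxyflavone",68112,Structure2D_CID_68112,test,Flavone,5,,
"3,6,4'-Trihydroxyflavone",688684,Structure2D_CID_688684,test,Flavonol,"3,6,4'",,
"3,4'-Dihydroxyflavone",688715,Structure2D_CID_688715,test,Flavonol,"3,4'",,
"(±)-Naringenin",932,Structure2D_CID_932,test,Flavanone,"5,7,4'",,
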