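rank,name,k2alpha,Id,IdwAverage,new_bone_formation_pct,ambiguous_parse
1,"Scutellarein",5.334,790.386,7.774,,False
2,"Morin",5.67,798.763,7.77,,True
3,"Daidzein",5.67,811.449,7.762,602,True
4,"Myricetin",5.109,710.672,7.646,,False
5,"Apigenin",5.109,717.251,7.641,,False
6,"Quercetin",5.253,717.251,7.641,556,False
7,"(±)-Taxifolin",12.063,3184.03,9.445,,False
8,"5,7,2'-Trihydroxyflavone",5.232,622.413,7.523,,False
9,"Genistein",4.885,645.406,7.502,520,False
10,"Rutin",4.885,655.079,7.493,,False
11,"Kaempferol",12.328,3499.12,9.59,,False
12,"Tamarixetin",4.885,660.411,7.488,,False
13,"Naringin",4.502,560.369,7.37,490,False
14,"Isorhamnetin",4.661,561.775,7.371,,False
15,"Chrysin",4.661,576.201,7.357,,False
16,"Galangin",4.661,578.975,7.357,,False
17,"Luteolin",4.661,586.848,7.347,,False
18,"Baicalein",4.661,587.476,7.347,,False
19,"Resokaempferol",4.438,508.035,7.208,,False
20,"3-Methyl galangin",4.438,528.263,7.187,,False
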