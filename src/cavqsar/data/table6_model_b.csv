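name,split,observed,predicted,residual
"5,7,2'-Trihydroxyflavone",train,2.013,2.003,-0.010
"Naringin",train,2.038,2.042,0.004
"(±)-Taxifolin",train,2.047,2.026,-0.021
"Quercetin",train,1.880,2.023,0.143
"Apigenin",train,2.040,1.999,-0.041
"Luteolin",train,2.055,2.012,-0.043
"Rutin",train,2.070,2.091,0.021
"Kaempferol",train,2.008,2.010,0.002
"Genistein",train,2.124,2.000,-0.124
"Baicalein",train,1.999,2.003,0.004
"Chrysin",train,1.850,1.987,0.137
"Resokaempferol",train,2.042,2.002,-0.040
"Galangin",train,1.950,1.997,0.047
"Isorhamnetin",train,1.950,2.023,0.073
"Morin",train,2.199,2.026,-0.173
"Myricetin",train,2.057,2.015,-0.042
"Scutellarein",train,1.995,2.029,0.034
"Tamarixetin",train,2.042,1.991,-0.051
"Daidzein",train,1.915,1.995,0.080
"3-Methyl galangin",train,1.932,1.976,0.044
"5-Hydroxyflavone",test,2.057,2.008,-0.049
"3,6,4'-Trihydroxyflavone",test,1.995,1.994,-0.001
"3,4'-Dihydroxyflavone",test,1.993,2.007,0.014
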