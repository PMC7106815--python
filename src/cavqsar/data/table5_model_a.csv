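name,split,observed,predicted,residual
"5,7,2'-Trihydroxyflavone",train,0.519,0.518,-0.001
"Naringin",train,0.519,0.468,-0.051
"(±)-Taxifolin",train,0.477,0.584,0.107
"Quercetin",train,0.792,0.590,-0.202
"Apigenin",train,0.462,0.490,0.028
"Luteolin",train,0.447,0.539,0.092
"Rutin",train,0.38,0.431,0.051
"Kaempferol",train,0.663,0.547,-0.116
"Genistein",train,0.580,0.490,-0.090
"Baicalein",train,0.462,0.499,0.037
"Chrysin",train,0.491,0.449,-0.042
"Resokaempferol",train,0.431,0.498,0.067
"Galangin",train,0.491,0.512,0.021
"Isorhamnetin",train,0.732,0.611,-0.121
"Morin",train,0.505,0.595,0.090
"Myricetin",train,0.556,0.630,0.074
"Scutellarein",train,0.431,0.534,0.103
"Tamarixetin",train,0.663,0.602,-0.061
"Daidzein",train,0.491,0.431,-0.060
"3-Methyl galangin",train,0.477,0.552,0.075
"5-Hydroxyflavone",test,0.398,0.389,-0.009
"3,6,4'-Trihydroxyflavone",test,0.462,0.484,0.022
"3,4'-Dihydroxyflavone",test,0.462,0.447,-0.015
"(±)-Naringenin",test,0.462,0.484,0.022
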