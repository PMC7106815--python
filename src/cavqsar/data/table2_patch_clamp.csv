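name,tau_act_control_ms,tau_act_control_sem,tau_act_drug_ms,tau_act_drug_sem,tau_act_significance,tau_inact_control_ms,tau_inact_control_sem,tau_inact_drug_ms,tau_inact_drug_sem,tau_inact_significance,n_cells,note
"Myricetin",3.1,0.2,3.6,0.4,,116.6,12.9,,,ND,10,"second activation constant 29.0 ± 7.3 reported"
"Quercetin",3.0,0.2,6.2,0.3,***,94.5,7.7,75.9,4.3,*,6,
"Genistein",3.1,0.4,3.8,0.3,*,112.0,7.9,133.0,11.5,*,7,
"Isorhamnetin",2.4,0.2,5.4,0.4,**,112.8,11.4,89.1,8.8,*,5,
"Luteolin",2.5,0.2,2.8,0.3,,115.8,11.1,113.6,15.3,,5,
"Apigenin",2.9,0.3,2.9,0.3,,100.2,2.6,109.6,8.2,,6,
"Chrysin",3.2,0.3,3.1,0.2,,97.0,8.6,70.8,3.2,**,6,
"Kaempferol",2.5,0.3,4.6,0.3,***,106.7,4.6,101.9,7.0,,6,
"Tamarixetin",2.3,0.1,4.6,0.3,***,97.1,7.5,98.9,10.3,,9,
"Rutin",2.3,0.2,2.4,0.3,,122.2,11.2,117.4,5.4,,6,
"(±)-Taxifolin",2.7,0.2,3.0,0.3,,117.2,10.4,111.5,5.5,,6,
"3,6,4'-Trihydroxyflavone",2.7,0.2,2.9,0.3,,116.7,17.8,114.0,15.7,,5,
"5,7,2'-Trihydroxyflavone",3.2,0.4,3.3,0.3,,104.6,9.4,103.1,4.7,,5,
"Scutellarein",2.4,0.2,2.7,0.2,,109.7,8.7,114.0,7.3,,6,
"Naringin",2.8,0.1,3.3,0.3,,122.4,16.1,109.1,14.1,,4,
"5-Hydroxyflavone",3.0,0.7,2.5,0.4,,92.0,4.8,85.5,1.4,,4,
"3,4'-Dihydroxyflavone",2.7,0.2,2.9,0.3,,100.8,9.7,98.9,10.4,,5,
"Daidzein",2.9,0.4,3.1,0.2,,92.2,9.0,110.2,12.9,*,5,
"Morin",2.7,0.2,3.2,0.1,*,127.9,10.6,158.1,16.8,*,5,
"(±)-Naringenin",2.7,0.2,2.9,0.3,,119.6,13.5,98.5,8.5,*,5,
"Resokaempferol",2.6,0.3,2.7,0.4,,114.4,14.0,110.1,9.6,,5,
"Baicalein",2.6,0.2,2.9,0.4,,102.9,9.4,99.7,5.7,,6,
"3-Methyl galangin",2.6,0.4,3.0,0.5,,114.9,5.9,82.3,10.0,*,4,
"Galangin",2.2,0.2,3.1,0.5,,99.3,7.5,89.2,5.1,,5,
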