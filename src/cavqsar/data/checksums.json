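{
  "table3_compounds.csv": "bdca3243e1e56e5fa97f5050fa2fc34577a33bd933cb886504610189e8afc619",
  "table5_model_a.csv": "c7bbaa84e35e8b8a952bdc224c398464c9fc6c4ce19f27e809efadcc490585cb",
  "table6_model_b.csv": "ccfad6fa85a7fb0961d173277deeaefd374762a89d8b2249a9761f60c72a295b",
  "table7_descriptors.csv": "4478fcc213bd8d9a1f1fd98bad4eaae0e8a3783804bf634ac2d871ed16a1d2cd",
  "table2_patch_clamp.csv": "a5c6453f5afe439602ac30eb540db0a5cae60a654c4f81b88db5cc2b37f84bc6",
  "models_table4.json": "b0c58f061239098a12ecec0f6e83377517b91b6783527256cf67266a2dde6536"
}
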