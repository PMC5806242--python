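Urea Cycle. Arginine and Proline Metabolism	supernatant panel	Arginine	Ornithine	Citrulline	Proline	Urea	Argininosuccinate	Ammonia	Hydroxyproline
Alanine And Aspartate Metabolism	supernatant panel	Alanine	Asparagine	Aspartic Acid
Glutamate Metabolism	supernatant panel	Glutamic Acid	Glutamine	GABA
Glycine, Serine And Threonine Metabolism	supernatant panel	Glycine	Serine	Threonine	Sarcosine
Glycolysis. Gluconeogenesis. Pyruvate Metabolism	supernatant panel	Glucose	Glyceric Acid	Lactic Acid	Malic Acid
Pentose Phosphate Pathway	supernatant panel	Ribose	Ribofuranose	Gluconic Acid 1.4-Lactone	Sedoheptulose-7-Phosphate
Valine. Leucine And Isoleucine Degradation	supernatant panel	Valine	Leucine	Isoleucine	2-Oxoisocaproic Acid
Cysteine And Methionine Metabolism	supernatant panel	Cysteine	Cystine	Methionine
Tyrosine Metabolism	supernatant panel	Tyrosine
Citric Acid Cycle	supernatant panel	Succinic Acid
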