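Genus	Species
Acinetobacter	Acinetobacter baumannii
Acinetobacter	Acinetobacter lwoffii
Aggregatibacter	Aggregatibacter actinomycetemcomitans
Bacteroides	Bacteroides fragilis
Bordetella	Bordetella pertussis
Borrelia	Borrelia burgdorferi
Brucella	Brucella melitensis
Campylobacter	Campylobacter jejuni
Campylobacter	Campylobacter coli
Chlamydia	Chlamydia trachomatis
Citrobacter	Citrobacter freundii
Clostridioides	Clostridioides difficile
Clostridium	Clostridium perfringens
Clostridium	Clostridium botulinum
Clostridium	Clostridium tetani
Corynebacterium	Corynebacterium diphtheriae
Enterococcus	Enterococcus faecalis
Enterococcus	Enterococcus faecium
Escherichia	Escherichia albertii
Francisella	Francisella tularensis
Fusobacterium	Fusobacterium nucleatum
Fusobacterium	Fusobacterium necrophorum
Haemophilus	Haemophilus influenzae
Helicobacter	Helicobacter pylori
Klebsiella	Klebsiella pneumoniae
Klebsiella	Klebsiella oxytoca
Legionella	Legionella pneumophila
Leptospira	Leptospira interrogans
Listeria	Listeria monocytogenes
Moraxella	Moraxella catarrhalis
Morganella	Morganella morganii
Mycobacterium	Mycobacterium tuberculosis
Mycobacterium	Mycobacterium leprae
Mycobacterium	Mycobacterium avium
Mycoplasma	Mycoplasma pneumoniae
Neisseria	Neisseria gonorrhoeae
Neisseria	Neisseria meningitidis
Pasteurella	Pasteurella multocida
Porphyromonas	Porphyromonas gingivalis
Prevotella	Prevotella copri
Prevotella	Prevotella intermedia
Proteus	Proteus mirabilis
Providencia	Providencia stuartii
Pseudomonas	Pseudomonas aeruginosa
Salmonella	Salmonella enterica
Serratia	Serratia marcescens
Shigella	Shigella flexneri
Shigella	Shigella dysenteriae
Shigella	Shigella sonnei
Staphylococcus	Staphylococcus aureus
Staphylococcus	Staphylococcus epidermidis
Stenotrophomonas	Stenotrophomonas maltophilia
Streptococcus	Streptococcus pyogenes
Streptococcus	Streptococcus pneumoniae
Streptococcus	Streptococcus agalactiae
Treponema	Treponema pallidum
Treponema	Treponema denticola
Ureaplasma	Ureaplasma urealyticum
Vibrio	Vibrio cholerae
Vibrio	Vibrio parahaemolyticus
Yersinia	Yersinia pestis
Yersinia	Yersinia enterocolitica
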