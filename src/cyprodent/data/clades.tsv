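clade	taxon
Cobitoidea	Gyrinocheilus aymonieri
Cobitoidea	Catostomus commersonii
Cobitoidea	Ictiobus cyprinellus
Cobitoidea	Misgurnus anguillicaudatus
Cyprininae	Acrossocheilus yunnanensis
Cyprininae	Barbus reinii
Cyprininae	Carassius auratus
Cyprininae	Carassius carassius
Cyprininae	Cyprinus carpio
Cyprininae	Gymnocypris przewalskii
Cyprininae	Epalzeorhynchos bicolor
Cyprininae	Epalzeorhynchos frenatum
Cyprininae	Puntius semifasciolatus
Cyprininae	Puntius tetrazona
Cyprininae	Schizothorax meridionalis
Rasborinae	Boraras brigittae
Rasborinae	Danio rerio
Rasborinae	Danionella translucida
Rasborinae	Esomus metallicus
Rasborinae	Luciosoma setigerum
Rasborinae	Rasbora borapetensis
Rasborinae	Rasbora trilineata
Rasborinae	Sundadanio axelrodi
Rasborinae	Trigonostigma heteromorpha
Cultrinae	Ctenopharyngodon idella
Cultrinae	Culter alburnus
Cultrinae	Elopichthys bambusa
Cultrinae	Opsariicthys bidens
Cultrinae	Xenocypris yunnanensis
Cultrinae	Zacco platypus
Gobioninae	Gobio gobio
Gobioninae	Hemibarbus maculatus
Gobioninae	Saurogobio dabryi
Leuciscinae	Abramis brama
Leuciscinae	Leucaspius delineatus
Leuciscinae	Leuciscus cephalus
Leuciscinae	Luxilus cornutus
Leuciscinae	Phoxinus phoxinus
Leuciscinae	Rutilus rutilus
Leuciscinae	Scardinius erythrophtalmus
Acheilognathinae	Rhodeus sericeus
Acheilognathinae	Tanakia lanceolata
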