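taxon	clade	superfamily	formula	row_count_only	shape	source	specimen_ref
Psilorhynchus balitora	Psilorhynchidae	Cyprinoidea	4		spoon	scanned	MNHN, 1931-056
Boraras brigittae	Rasborinae	Cyprinoidea	2,5-(4,2)		spoon	scanned	Pet shop
Danio rerio	Rasborinae	Cyprinoidea	2,4,5		spoon	scanned	Pet shop
Danionella translucida	Rasborinae	Cyprinoidea		1		literature	Jayaram 1999
Esomus metallicus	Rasborinae	Cyprinoidea	5-(4)		compressed	scanned	MNHN, 1987-1355
Laubuca laubuca	Rasborinae	Cyprinoidea	2,4,5-(4,4,2)		spoon	scanned	MNHN, 1983-0214
Luciosoma setigerum	Rasborinae	Cyprinoidea	2,4,5		spoon	scanned	MNHN, 1994-0232
Opsaridium christyi	Rasborinae	Cyprinoidea	3,5		spoon	scanned	MNHN, 1986-0416
Rasbora borapetensis	Rasborinae	Cyprinoidea	4,5		spoon	scanned	MNHN, 1983-0249
Rasbora einthoveni	Rasborinae	Cyprinoidea	2,4,5		spoon	scanned	MNHN, 1986-0228
Rasbora trilineata	Rasborinae	Cyprinoidea	2,4,5		spoon	scanned	Pet shop
Sundadanio axelrodi	Rasborinae	Cyprinoidea	2,4-(5,2,1)		spoon	scanned	MNHN, 1982-0681
Trigonostigma heteromorpha	Rasborinae	Cyprinoidea	2,5-(5,2,2)		spoon	scanned	Pet shop
Acrossocheilus yunnanensis	Cyprininae	Cyprinoidea	2,3,5		spoon	scanned	MNHN, 1949-0037
Barbus reinii	Cyprininae	Cyprinoidea	2,3,5		spoon	literature	Talwar & Jhingran 1991
Carassius auratus	Cyprininae	Cyprinoidea	4		compressed	scanned	Pet shop
Carassius carassius	Cyprininae	Cyprinoidea	4		compressed	dissected	LSA
Cyprinus carpio	Cyprininae	Cyprinoidea	1,1,3		molariform	dissected	LSA
Gymnocypris przewalskii	Cyprininae	Cyprinoidea		2		literature	Talwar & Jhingran 1991
Epalzeorhynchos bicolor	Cyprininae	Cyprinoidea	2,4,5		spatula	scanned	Pet shop
Epalzeorhynchos frenatum	Cyprininae	Cyprinoidea	2,4,5		spatula	scanned	Pet shop
Puntius semifasciolatus	Cyprininae	Cyprinoidea	2,3,4-(5,3,2)		spoon	scanned	Pet shop
Puntius tetrazona	Cyprininae	Cyprinoidea	2,3,4		spoon	scanned	Pet shop
Schizothorax meridionalis	Cyprininae	Cyprinoidea	2,3,5		spoon	literature	Talwar & Jhingran 1991
Ctenopharyngodon idella	Cultrinae	Cyprinoidea	2,4		compressed	literature	Stock 2007
Culter alburnus	Cultrinae	Cyprinoidea	2,4,4-(5,4,2)		spoon	scanned	MNHN, 1934-0213
Elopichthys bambusa	Cultrinae	Cyprinoidea	2,4,5		spoon	literature	Chu 1935
Opsariicthys bidens	Cultrinae	Cyprinoidea	1,4,5		spoon	literature	Chu 1935
Xenocypris yunnanensis	Cultrinae	Cyprinoidea	2,3,5-(6,3,2)		compressed	scanned	MNHN, 1949-0042
Zacco platypus	Cultrinae	Cyprinoidea	1,4,5		spoon	literature	Chu 1935
Rhodeus sericeus	Acheilognathinae	Cyprinoidea	5		compressed	scanned	Pet shop
Tanakia lanceolata	Acheilognathinae	Cyprinoidea	5		compressed	scanned	MNHN, 1984-0419
Tanichthys albonubes	incertae-sedis	Cyprinoidea	1,4-(5,1)		compressed	scanned	Pet shop
Gobio gobio	Gobioninae	Cyprinoidea	3,5-(5,2)		spoon	scanned	LSA
Hemibarbus maculatus	Gobioninae	Cyprinoidea	1,3,5			literature	Chu 1935
Saurogobio dabryi	Gobioninae	Cyprinoidea	5			literature	Chu 1935
Tinca tinca	Tincinae	Cyprinoidea	4-(5)		compressed	dissected	LSA
Abramis brama	Leuciscinae	Cyprinoidea	5		compressed	literature	Jordan 1907
Leucaspius delineatus	Leuciscinae	Cyprinoidea	1,4-(5,1)		compressed	scanned	LSA
Leuciscus cephalus	Leuciscinae	Cyprinoidea	2,5		compressed	literature	Regan 1911
Luxilus cornutus	Leuciscinae	Cyprinoidea	4			literature	Regan 1911
Phoxinus phoxinus	Leuciscinae	Cyprinoidea	2,4-(5,2)		spoon	literature	Heckel 1843
Rutilus rutilus	Leuciscinae	Cyprinoidea	5-(6)		compressed	scanned	LSA
Scardinius erythrophtalmus	Leuciscinae	Cyprinoidea	3,5		saw	scanned	LSA
Carpiodes microstomus	Catostomidae	Cobitoidea	50		conical	scanned	MNHN, 1905-0340
Catostomus commersonii	Catostomidae	Cobitoidea	30		conical	scanned	MNHN, 1994-0301
Ictiobus cyprinellus	Catostomidae	Cobitoidea	55		conical	scanned	MNHN, 2002-0352
Misgurnus anguillicaudatus	Cobitidae	Cobitoidea	14-(16)		conical	scanned	Pet shop
Gyrinocheilus aymonieri	Gyrinocheilidae	Cobitoidea		0		literature	Nelson 2006
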