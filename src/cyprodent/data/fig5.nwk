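[ Hand transcription of the Bayesian 50%-majority-rule consensus topology for 45
  Cypriniformes species plus the outgroup Astyanax mexicanus. Branch lengths are
  intentionally unassigned (the published analysis does not report them); assign
  lengths with cyprodent.trees.assign_branch_lengths before likelihood work.
  The transcription respects the seven constrained monophyletic clades
  (Cobitoidea, Cyprininae, Rasborinae, Cultrinae, Gobioninae, Leuciscinae,
  Acheilognathinae), the basal Cobitoidea/Cyprinoidea split, Psilorhynchus
  balitora basal within Cyprinoidea, and the early-diverging placement of
  Cyprininae, Rasborinae and Cultrinae relative to Gobioninae, Tincinae and
  Leuciscinae. Within-clade resolution too shallow to read reliably from the
  printed figure follows standard cyprinid phylogenies. Internal node labels
  name major clades; posterior probabilities are not reproduced. ]
(Astyanax_mexicanus,((Gyrinocheilus_aymonieri,((Catostomus_commersonii,Ictiobus_cyprinellus)Catostomidae,Misgurnus_anguillicaudatus))Cobitoidea,(Psilorhynchus_balitora,(((Epalzeorhynchos_bicolor,Epalzeorhynchos_frenatum),((Puntius_semifasciolatus,Puntius_tetrazona),((Cyprinus_carpio,(Carassius_auratus,Carassius_carassius)),(Acrossocheilus_yunnanensis,(Barbus_reinii,(Schizothorax_meridionalis,Gymnocypris_przewalskii))))))Cyprininae,((Luciosoma_setigerum,(Esomus_metallicus,((Sundadanio_axelrodi,(Danionella_translucida,Danio_rerio)),(Boraras_brigittae,(Trigonostigma_heteromorpha,(Rasbora_borapetensis,Rasbora_trilineata))))))Rasborinae,(((Opsariicthys_bidens,Zacco_platypus),(Ctenopharyngodon_idella,(Elopichthys_bambusa,(Culter_alburnus,Xenocypris_yunnanensis))))Cultrinae,((Rhodeus_sericeus,Tanakia_lanceolata)Acheilognathinae,(Tanichthys_albonubes,((Hemibarbus_maculatus,(Gobio_gobio,Saurogobio_dabryi))Gobioninae,(Tinca_tinca,((Phoxinus_phoxinus,Luxilus_cornutus),((Leuciscus_cephalus,Scardinius_erythrophtalmus),(Leucaspius_delineatus,(Abramis_brama,Rutilus_rutilus))))Leuciscinae))))))))Cyprinoidea)Cypriniformes);
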