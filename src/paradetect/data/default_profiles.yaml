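# Default host-parasite pair profiles for the synthetic cohort generator.
#
# prevalence / mean_abundance are the published pooled summaries for the 27
# screened pairs (fraction of hosts infected; mean parasites per host
# including zeros).  stage, group and organs are SYNTHETIC assignments:
# biologically plausible labels consistent with the reported composition
# (adult and larval trematodes/nematodes, larval cestodes, adult
# acanthocephalans, adult leeches) and chosen so the moderator designs of
# the two meta-regressions are full rank.  Dispersion is calibrated from
# (prevalence, mean_abundance) at load time; treatment_log_ratio defaults
# to 0 (no preservation effect).
profiles:
  # Walleye pollock (n = 109)
  - {taxon: "Trematode metacercariae", host_species: pollock, group: Trematoda,
     stage: larva, organs: [muscle, eye], prevalence: 0.1101, mean_abundance: 0.5505}
  - {taxon: "Gill metacercariae", host_species: pollock, group: Trematoda,
     stage: larva, organs: [gills], prevalence: 0.6147, mean_abundance: 14.2385}
  - {taxon: "Lepidapedean sp.", host_species: pollock, group: Trematoda,
     stage: adult, organs: [intestine, pyloric_ceca], prevalence: 0.2294, mean_abundance: 1.4128}
  - {taxon: "Hemiuridean sp.", host_species: pollock, group: Trematoda,
     stage: adult, organs: [stomach], prevalence: 0.1927, mean_abundance: 0.7890}
  - {taxon: "Anisakis sp.", host_species: pollock, group: Nematoda,
     stage: larva, organs: [body_cavity, liver], prevalence: 0.3211, mean_abundance: 0.9174}
  - {taxon: "Contracecum sp.", host_species: pollock, group: Nematoda,
     stage: larva, organs: [body_cavity, liver], prevalence: 0.3211, mean_abundance: 1.2661}
  - {taxon: "Hysterothylacium sp.", host_species: pollock, group: Nematoda,
     stage: larva, organs: [stomach, intestine, pyloric_ceca], prevalence: 0.3394, mean_abundance: 2.1835}
  - {taxon: "Nybelinia surmenicola", host_species: pollock, group: Cestoda,
     stage: larva, organs: [stomach, body_cavity], prevalence: 0.0734, mean_abundance: 0.1468}
  - {taxon: "Echinorhynchus gadii", host_species: pollock, group: Acanthocephala,
     stage: adult, organs: [intestine], prevalence: 0.1560, mean_abundance: 0.4587}
  # Eulachon (n = 70)
  - {taxon: "Lecithaster sp.", host_species: eulachon, group: Trematoda,
     stage: adult, organs: [stomach], prevalence: 0.0857, mean_abundance: 0.4857}
  - {taxon: "Lecithasteridean sp.", host_species: eulachon, group: Trematoda,
     stage: adult, organs: [intestine], prevalence: 0.1143, mean_abundance: 0.3714}
  - {taxon: "Pseudoterranova sp.", host_species: eulachon, group: Nematoda,
     stage: larva, organs: [heart, body_cavity, muscle], prevalence: 0.6429, mean_abundance: 4.8571}
  - {taxon: "Anisakis sp.", host_species: eulachon, group: Nematoda,
     stage: larva, organs: [body_cavity], prevalence: 0.0857, mean_abundance: 0.2000}
  - {taxon: "Hysterothylacium sp.", host_species: eulachon, group: Nematoda,
     stage: larva, organs: [intestine], prevalence: 0.2571, mean_abundance: 0.9143}
  - {taxon: "Tetraphyllidean sp.", host_species: eulachon, group: Cestoda,
     stage: larva, organs: [intestine], prevalence: 0.1000, mean_abundance: 0.2000}
  # English sole (n = 99)
  - {taxon: "Trematode metacercariae", host_species: english_sole, group: Trematoda,
     stage: larva, organs: [muscle], prevalence: 0.0606, mean_abundance: 0.5252}
  - {taxon: "Fin metacercariae", host_species: english_sole, group: Trematoda,
     stage: larva, organs: [fins], prevalence: 0.3737, mean_abundance: 204.5455}
  - {taxon: "Derogenes sp.", host_species: english_sole, group: Trematoda,
     stage: adult, organs: [stomach], prevalence: 0.0505, mean_abundance: 0.1212}
  - {taxon: "Larval nematode", host_species: english_sole, group: Nematoda,
     stage: larva, organs: [body_cavity, muscle], prevalence: 0.2525, mean_abundance: 4.4040}
  - {taxon: "Cucullanus sp.", host_species: english_sole, group: Nematoda,
     stage: adult, organs: [intestine], prevalence: 0.8687, mean_abundance: 24.6667}
  - {taxon: "Nematode 4", host_species: english_sole, group: Nematoda,
     stage: larva, organs: [kidney], prevalence: 0.1818, mean_abundance: 2.0606}
  - {taxon: "Nematode 3", host_species: english_sole, group: Nematoda,
     stage: larva, organs: [liver], prevalence: 0.0909, mean_abundance: 0.2222}
  - {taxon: "Nematode 2", host_species: english_sole, group: Nematoda,
     stage: larva, organs: [gonad], prevalence: 0.0909, mean_abundance: 0.2828}
  - {taxon: "Nematode 1", host_species: english_sole, group: Nematoda,
     stage: larva, organs: [body_cavity], prevalence: 0.0808, mean_abundance: 0.2424}
  - {taxon: "Clavinema mariae", host_species: english_sole, group: Nematoda,
     stage: adult, organs: [fins], prevalence: 0.7778, mean_abundance: 28.6262}
  - {taxon: "Encysted larval nematode", host_species: english_sole, group: Nematoda,
     stage: larva, organs: [muscle], prevalence: 0.1111, mean_abundance: 0.2828}
  - {taxon: "Oceanobdella pallida", host_species: english_sole, group: Hirudinea,
     stage: adult, organs: [buccal_cavity, gills, fins], prevalence: 0.3333, mean_abundance: 0.9899}
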