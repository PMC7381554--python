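specimen_id,species,standard_length_mm,treatment,tow_id,taxon,group,stage,organ,count
pollock_001,pollock,150,control,,Anisakis sp.,Nematoda,larva,body_cavity,2
pollock_001,pollock,150,control,,Contracecum sp.,Nematoda,larva,liver,0
pollock_001,pollock,150,control,,Hysterothylacium sp.,Nematoda,larva,stomach,1
pollock_001,pollock,150,control,,Hemiuridean sp.,Trematoda,adult,stomach,0
pollock_001,pollock,150,control,,Nybelinia surmenicola,Cestoda,larva,body_cavity,0
pollock_001,pollock,150,control,,Echinorhynchus gadii,Acanthocephala,adult,intestine,1
pollock_002,pollock,162,preserved,,Anisakis sp.,Nematoda,larva,body_cavity,0
pollock_002,pollock,162,preserved,,Contracecum sp.,Nematoda,larva,body_cavity,3
pollock_002,pollock,162,preserved,,Hysterothylacium sp.,Nematoda,larva,pyloric_ceca,4
pollock_002,pollock,162,preserved,,Hemiuridean sp.,Trematoda,adult,stomach,1
pollock_002,pollock,162,preserved,,Nybelinia surmenicola,Cestoda,larva,stomach,0
pollock_002,pollock,162,preserved,,Echinorhynchus gadii,Acanthocephala,adult,intestine,0
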