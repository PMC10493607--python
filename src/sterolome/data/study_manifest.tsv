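sample_id	species	family	order	tissue	role	pollination	reward	pollinator	pollen_mass_mg
alnus_glutinosa_pollen	Alnus glutinosa	Betulaceae	Fagales	pollen	sample	wind	NA	NA	NA
alnus_glutinosa_leaf	Alnus glutinosa	Betulaceae	Fagales	leaf	sample	wind	NA	NA	NA
araucaria_araucana_leaf	Araucaria araucana	Araucariaceae	Araucales	leaf	sample	wind	NA	NA	NA
artemisia_vulgaris_pollen	Artemisia vulgaris	Asteraceae	Asterales	pollen	sample	wind	NA	NA	NA
artemisia_vulgaris_leaf	Artemisia vulgaris	Asteraceae	Asterales	leaf	sample	wind	NA	NA	NA
beta_vulgaris_pollen	Beta vulgaris	Amaranthaceae	Caryophyllales	pollen	sample	wind	NA	NA	NA
beta_vulgaris_leaf	Beta vulgaris	Amaranthaceae	Caryophyllales	leaf	sample	wind	NA	NA	NA
brugmansia_sanguinea_pollen	Brugmansia sanguinea	Solanaceae	Solanales	pollen	sample	animal	nectar	NA	NA
brugmansia_sanguinea_leaf	Brugmansia sanguinea	Solanaceae	Solanales	leaf	sample	animal	nectar	NA	NA
buddleja_davidii_pollen	Buddleja davidii	Scrophulariaceae	Lamiales	pollen	sample	animal	nectar	NA	NA
buddleja_davidii_leaf	Buddleja davidii	Scrophulariaceae	Lamiales	leaf	sample	animal	nectar	NA	NA
buddleja_officinalis_leaf	Buddleja officinalis	Scrophulariaceae	Lamiales	leaf	sample	animal	nectar	NA	NA
chenopodium_album_pollen	Chenopodium album	Amaranthaceae	Caryophyllales	pollen	sample	wind	NA	NA	NA
chenopodium_album_leaf	Chenopodium album	Amaranthaceae	Caryophyllales	leaf	sample	wind	NA	NA	NA
chenopodium_sp_leaf	Chenopodium sp.	Amaranthaceae	Caryophyllales	leaf	sample	wind	NA	NA	NA
corylus_avellana_pollen	Corylus avellana	Betulaceae	Fagales	pollen	sample	wind	NA	NA	NA
corylus_avellana_leaf	Corylus avellana	Betulaceae	Fagales	leaf	sample	wind	NA	NA	NA
cytisus_scoparius_pollen	Cytisus scoparius	Fabaceae	Fabales	pollen	sample	animal	pollen	NA	NA
cytisus_scoparius_leaf	Cytisus scoparius	Fabaceae	Fabales	leaf	sample	animal	pollen	NA	NA
dactylis_glomerata_leaf	Dactylis glomerata	Poaceae	Poales	leaf	sample	wind	NA	NA	NA
eschscholzia_californica_pollen	Eschscholzia californica	Papaveraceae	Ranunculales	pollen	sample	animal	pollen	NA	NA
eschscholzia_californica_leaf	Eschscholzia californica	Papaveraceae	Ranunculales	leaf	sample	animal	pollen	NA	NA
fuchsia_denticulata_leaf	Fuchsia denticulata	Onagraceae	Myrtales	leaf	sample	animal	nectar	NA	NA
garrya_elliptica_pollen	Garrya elliptica	Garryaceae	Garryales	pollen	sample	wind	NA	NA	NA
garrya_elliptica_leaf	Garrya elliptica	Garryaceae	Garryales	leaf	sample	wind	NA	NA	NA
gunnera_manicata_pollen	Gunnera manicata	Gunneraceae	Gunnerales	pollen	sample	wind	NA	NA	NA
gunnera_manicata_leaf	Gunnera manicata	Gunneraceae	Gunnerales	leaf	sample	wind	NA	NA	NA
haemanthus_albiflos_pollen	Haemanthus albiflos	Amaryllidaceae	Asparagales	pollen	sample	animal	nectar	NA	NA
haemanthus_albiflos_leaf	Haemanthus albiflos	Amaryllidaceae	Asparagales	leaf	sample	animal	nectar	NA	NA
helianthemum_croceum_pollen	Helianthemum croceum	Cistaceae	Malvales	pollen	sample	animal	pollen	NA	NA
helianthemum_croceum_leaf	Helianthemum croceum	Cistaceae	Malvales	leaf	sample	animal	pollen	NA	NA
helix_hedera_pollen	Helix hedera	Araliaceae	Apiales	pollen	sample	animal	nectar	NA	NA
hibbertia_grossulariifolia_leaf	Hibbertia grossulariifolia	Dilleniaceae	Dilleniales	leaf	sample	animal	pollen	NA	NA
hypericum_polyphyllum_pollen	Hypericum polyphyllum	Hyperiaceae	Malpighiales	pollen	sample	animal	pollen	NA	NA
hypericum_polyphyllum_leaf	Hypericum polyphyllum	Hyperiaceae	Malpighiales	leaf	sample	animal	pollen	NA	NA
juglans_nigra_pollen	Juglans nigra	Juglandaceae	Fagales	pollen	sample	wind	NA	NA	NA
juglans_nigra_leaf	Juglans nigra	Juglandaceae	Fagales	leaf	sample	wind	NA	NA	NA
lilium_martagon_pollen	Lilium martagon	Liliaceae	Liliales	pollen	sample	animal	nectar	NA	NA
lilium_martagon_leaf	Lilium martagon	Liliaceae	Liliales	leaf	sample	animal	nectar	NA	NA
lysimachia_punctata_pollen	Lysimachia punctata	Primulaceae	Ericales	pollen	sample	animal	pollen	NA	NA
lysimachia_punctata_leaf	Lysimachia punctata	Primulaceae	Ericales	leaf	sample	animal	pollen	NA	NA
lysimachia_vulgaris_pollen	Lysimachia vulgaris	Primulaceae	Ericales	pollen	sample	animal	pollen	NA	NA
lysimachia_vulgaris_leaf	Lysimachia vulgaris	Primulaceae	Ericales	leaf	sample	animal	pollen	NA	NA
papaver_rhoeas_pollen	Papaver rhoeas	Papaveraceae	Ranunculales	pollen	sample	animal	pollen	NA	NA
papaver_rhoeas_leaf	Papaver rhoeas	Papaveraceae	Ranunculales	leaf	sample	animal	pollen	NA	NA
passiflora_citrina_pollen	Passiflora citrina	Passifloraceae	Malpighiales	pollen	sample	animal	nectar	NA	NA
passiflora_citrina_leaf	Passiflora citrina	Passifloraceae	Malpighiales	leaf	sample	animal	nectar	NA	NA
penstemon_barbatus_pollen	Penstemon barbatus	Plantaginaceae	Lamiales	pollen	sample	animal	nectar	NA	NA
penstemon_barbatus_leaf	Penstemon barbatus	Plantaginaceae	Lamiales	leaf	sample	animal	nectar	NA	NA
petunia_exserta_pollen	Petunia exserta	Solanaceae	Solanales	pollen	sample	animal	nectar	NA	NA
petunia_exserta_leaf	Petunia exserta	Solanaceae	Solanales	leaf	sample	animal	nectar	NA	NA
pinus_coulteri_pollen	Pinus coulteri	Pinaeceae	Pinales	pollen	sample	wind	NA	NA	NA
pinus_coulteri_leaf	Pinus coulteri	Pinaeceae	Pinales	leaf	sample	wind	NA	NA	NA
plantago_lanceolata_pollen	Plantago lanceolata	Plantaginaceae	Lamiales	pollen	sample	wind	NA	NA	NA
plantago_lanceolata_leaf	Plantago lanceolata	Plantaginaceae	Lamiales	leaf	sample	wind	NA	NA	NA
populus_nigra_pollen	Populus nigra	Salicaceae	Malpighiales	pollen	sample	wind	NA	NA	NA
populus_nigra_leaf	Populus nigra	Salicaceae	Malpighiales	leaf	sample	wind	NA	NA	NA
quercus_ilex_pollen	Quercus ilex	Fagaceae	Fagales	pollen	sample	wind	NA	NA	NA
quercus_ilex_leaf	Quercus ilex	Fagaceae	Fagales	leaf	sample	wind	NA	NA	NA
rosa_canina_pollen	Rosa canina	Rosaceae	Rosales	pollen	sample	animal	pollen	NA	NA
rosa_canina_leaf	Rosa canina	Rosaceae	Rosales	leaf	sample	animal	pollen	NA	NA
rumex_sanguineus_pollen	Rumex sanguineus	Polygonaceae	Caryophyllales	pollen	sample	wind	NA	NA	NA
salix_sp_pollen	Salix sp.	Salicaceae	Malpighiales	pollen	sample	wind	NA	NA	NA
solanum_dulcamara_pollen	Solanum dulcamara	Solanaceae	Solanales	pollen	sample	animal	pollen	NA	NA
solanum_dulcamara_leaf	Solanum dulcamara	Solanaceae	Solanales	leaf	sample	animal	pollen	NA	NA
strelitzia_reginae_pollen	Strelitzia reginae	Strelitziaceae	Zingiberales	pollen	sample	animal	nectar	NA	NA
strelitzia_reginae_leaf	Strelitzia reginae	Strelitziaceae	Zingiberales	leaf	sample	animal	nectar	NA	NA
triticum_aestivum_pollen	Triticum aestivum	Poaceae	Poales	pollen	sample	wind	NA	NA	NA
triticum_aestivum_leaf	Triticum aestivum	Poaceae	Poales	leaf	sample	wind	NA	NA	NA
urtica_dioica_pollen	Urtica dioica	Urticaceae	Rosales	pollen	sample	wind	NA	NA	NA
urtica_dioica_leaf	Urtica dioica	Urticaceae	Rosales	leaf	sample	wind	NA	NA	NA
blank_solvent_1	NA	NA	NA	NA	blank_solvent	NA	NA	NA	NA
blank_solvent_2	NA	NA	NA	NA	blank_solvent	NA	NA	NA	NA
blank_solvent_3	NA	NA	NA	NA	blank_solvent	NA	NA	NA	NA
blank_solvent_4	NA	NA	NA	NA	blank_solvent	NA	NA	NA	NA
blank_solvent_5	NA	NA	NA	NA	blank_solvent	NA	NA	NA	NA
blank_solvent_6	NA	NA	NA	NA	blank_solvent	NA	NA	NA	NA
blank_solvent_7	NA	NA	NA	NA	blank_solvent	NA	NA	NA	NA
blank_extraction_1	NA	NA	NA	NA	blank_extraction	NA	NA	NA	NA
blank_extraction_2	NA	NA	NA	NA	blank_extraction	NA	NA	NA	NA
blank_extraction_3	NA	NA	NA	NA	blank_extraction	NA	NA	NA	NA
qc_2.5mg_1	polyfloral QC	NA	NA	pollen	qc	NA	NA	NA	2.5
qc_2.5mg_2	polyfloral QC	NA	NA	pollen	qc	NA	NA	NA	2.5
qc_2.5mg_3	polyfloral QC	NA	NA	pollen	qc	NA	NA	NA	2.5
qc_5mg_1	polyfloral QC	NA	NA	pollen	qc	NA	NA	NA	5
qc_5mg_2	polyfloral QC	NA	NA	pollen	qc	NA	NA	NA	5
qc_5mg_3	polyfloral QC	NA	NA	pollen	qc	NA	NA	NA	5
qc_10mg_1	polyfloral QC	NA	NA	pollen	qc	NA	NA	NA	10
qc_10mg_2	polyfloral QC	NA	NA	pollen	qc	NA	NA	NA	10
qc_10mg_3	polyfloral QC	NA	NA	pollen	qc	NA	NA	NA	10
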