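taxon	blocks
Leptocylindrus_danicus	27 26 -28 -11 -14 -12 -22 -18 -17 -5 -6 -7 -8 -9 -10 1 2 3 4 -16 -15 -23 21 20 19 13 25 24 42 39 33 34 35 36 37 32 -31 -30 -29 -38 -40 -41
Probosica_sp.	-1 2 3 4 -5 -6 -7 -8 -9 -10 11 -12 -13 -14 15 16 17 18 -19 -20 -21 22 -23 -24 25 -26 -27 -28 29 30 31 -32 33 34 35 36 37 -38 -39 -40 -41 -42
Actinocyclus_subtilis	2 3 4 -13 -19 -20 -21 -1 -11 -14 -12 -22 -18 -17 -5 -6 -7 -8 -9 -10 23 15 16 28 27 26 25 24 42 41 40 39 38 29 30 31 33 34 35 36 37 32
Coscinodiscus_radiatus	2 3 4 -13 -19 -20 -21 -1 -11 -14 -12 -22 -18 -17 -5 -6 -7 -8 -9 -10 23 15 16 28 27 26 25 24 42 41 40 39 38 29 30 31 33 34 35 36 37 32
Rhizosolenia_setigera	2 3 4 -13 -19 -20 -21 -1 -11 -14 -12 -22 -18 -17 -5 -6 -7 -8 -9 -10 23 15 16 28 27 26 25 24 42 41 -32 -37 -36 -35 -34 -33 29 30 31 -38 -39 -40
Guinardia_striata	2 3 4 -13 23 15 16 28 27 26 10 9 8 7 6 5 17 18 22 12 14 11 1 21 20 19 -41 -42 -24 -25 -32 -37 -36 -35 -34 -33 29 30 31 -38 -39 -40
Rhizosolenia_fallax	2 3 4 -13 -19 -20 -21 -1 -11 -14 -12 -22 -18 -17 -5 -6 -7 -8 -9 -10 -26 -27 -28 -16 -15 -23 25 24 42 41 -32 -37 -36 -35 -34 -33 29 30 31 -38 -39 -40
Rhizosolenia_imbricate	-4 -3 -2 -13 -19 -20 -21 -1 -11 -14 -12 -22 -18 -17 -5 -6 -7 -8 -9 -10 -26 -27 -28 -16 -15 -23 25 24 42 41 -32 -37 -36 40 39 38 29 30 31 33 34 35
Lithodesmium_undulatum	2 3 4 -13 -19 -20 -21 -1 -11 18 22 12 14 -17 -5 -6 -7 -8 -9 -10 23 15 16 28 27 26 25 29 30 31 33 34 35 36 37 32 -38 -39 -40 -41 -42 -24
Eunotogramma_sp.	22 12 14 11 16 28 27 26 2 3 4 -13 -19 -20 -21 -18 -17 -5 -6 -7 -8 -9 -10 15 -23 1 25 24 42 41 40 39 38 30 31 33 34 35 36 37 32 -29
Roundia_cardiophora	2 3 4 17 18 22 -26 -27 -28 -16 12 14 10 9 8 7 6 5 11 23 -15 1 21 20 19 13 25 -38 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 32
Thalassiosira_weissflogii	2 3 4 17 18 22 -26 -27 -28 -16 12 14 10 9 8 7 6 5 11 23 -15 1 21 20 19 13 25 -38 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 32
Discostella_pseudostelligera	2 3 4 17 18 22 -26 -27 -28 -16 12 14 10 9 8 7 6 5 11 23 -15 1 21 20 19 13 25 -38 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 32
Thalassiosira_oceania	2 3 4 17 18 28 27 26 16 22 23 -15 -1 21 20 19 -5 -6 -7 -8 -9 -10 -14 -12 11 13 25 -38 -39 24 42 41 40 32 -31 -30 -29 33 34 35 36 37
Cyclotella_nana	2 3 4 17 18 22 -26 -27 -28 -16 12 14 10 9 8 7 6 5 11 23 -15 1 21 20 19 13 25 -38 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 32
Cyclotella_sp._L04_2	2 3 4 16 28 27 26 -22 -18 -17 12 14 10 9 8 7 6 5 11 23 -15 1 21 20 19 13 25 -38 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 32
Cyclotella_sp._WC03_2	2 3 4 16 28 27 26 -22 -18 -17 12 14 10 9 8 7 6 5 11 23 -15 1 21 20 19 13 25 -38 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 32
Plagiogrammopsis_van_heurckii	2 3 4 10 9 8 7 6 5 17 18 22 12 14 1 21 20 19 13 15 16 23 -26 -27 -28 11 25 24 42 41 40 39 38 -29 30 31 33 34 35 36 37 32
Trieres_sinensis	2 3 4 10 9 8 7 6 5 17 18 22 12 14 1 21 20 19 13 15 16 28 27 26 23 11 25 -38 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 32
Triceratium_dubium	2 3 4 10 9 8 7 6 5 17 18 22 12 14 1 21 20 19 13 15 16 28 27 26 23 11 25 -38 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 32
Cerataulina_daemon	2 3 4 -23 10 9 8 7 6 5 17 18 22 12 14 1 21 20 19 13 15 16 28 27 26 11 25 -38 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 32
Acanthoceras_zachariasii	10 9 8 2 3 4 7 6 5 17 18 22 12 14 1 21 20 19 13 15 16 28 27 26 23 11 25 29 30 31 33 34 35 36 37 32 24 42 41 40 39 38
Chaetoceros_simplex	10 9 8 2 3 4 7 6 5 17 18 22 12 14 1 -19 -20 -21 13 15 16 28 27 26 23 11 25 29 30 31 33 34 35 36 37 32 24 42 41 40 39 38
Attheya_logicornis	2 3 4 13 -19 -20 -21 23 15 16 1 28 27 26 22 12 14 -18 -17 -5 -6 -7 -8 -9 -10 11 25 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 32 38
Biddulphia_tridens	2 3 4 13 -19 -20 -21 23 15 16 28 27 26 1 -14 -12 -22 -18 -17 -5 -6 -7 -8 -9 -10 11 25 29 30 31 33 34 35 36 37 32 24 42 41 40 39 38
Biddulphia_biddulphiana	2 3 4 13 -19 -20 -21 23 15 16 28 27 26 1 -14 -12 -22 -18 -17 -5 -6 -7 -8 -9 -10 11 25 29 30 31 33 34 35 36 37 32 24 42 41 40 39 38
Asterionellopsis_glacialis	2 3 4 13 -23 -1 21 20 19 15 16 -11 -14 -12 -22 -18 -17 10 9 8 7 6 5 -26 -27 -28 25 -38 33 34 35 36 37 -39 -40 -41 -42 -24 -31 -30 -29 32
Plagiogramma_staurophorum	-21 1 23 -4 -3 -2 10 9 8 7 6 5 17 18 22 12 14 11 -16 -15 28 27 26 20 19 13 25 -38 -39 -40 -41 -42 -24 -29 30 31 33 34 35 36 37 32
Psammoneis_obaidii	7 6 5 2 3 4 -13 -19 -20 -21 1 23 15 16 -11 17 18 22 12 14 -26 -27 -28 10 9 8 25 -38 32 29 30 31 33 34 35 36 37 24 42 41 40 39
Asterionella_formosa	2 3 4 -26 -27 -28 10 9 8 7 6 5 17 18 22 12 14 23 15 16 -11 1 21 20 19 13 25 -38 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 -32
Astrosyne_radiata	-20 -21 -1 23 15 16 -11 -14 -12 -22 -18 -17 -5 -6 -7 -8 -9 -10 28 27 19 -13 -4 -3 -2 26 25 -38 30 31 29 -32 33 34 35 36 37 24 42 41 40 39
Synedra_acus	2 3 4 -13 -19 -20 -21 1 23 15 16 -11 -14 -12 -22 -18 -17 -5 -6 -7 -8 -9 -10 28 27 26 25 -38 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 32
Licmorphora_sp.	-4 -3 -2 -26 -27 -28 10 9 8 7 6 5 17 18 22 12 14 11 -16 -15 -23 -1 21 20 19 13 25 -38 -39 -40 -41 -42 -24 29 30 31 -32 -37 -36 -35 -34 -33
Eunotia_naegelii	2 3 4 -13 -19 -20 -21 -1 23 15 16 -11 -14 -12 -22 -18 -17 -5 -6 -7 -8 -9 -10 -26 -27 -28 25 -38 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 32
Cylindrotheca_closterium	-2 -23 9 8 7 6 5 17 18 22 12 14 11 -16 -15 -13 -19 -20 -21 1 -26 -27 -28 -10 25 -32 33 34 35 36 37 29 30 31 24 42 41 40 39 38 -4 -3
Seminavis_robusta	-4 -3 -2 -13 -19 -20 -21 -1 23 15 16 -11 -14 -12 -22 -18 -17 -5 -6 -7 -8 -9 -10 26 -27 -28 25 -38 -39 -40 -41 -42 -24 -37 -36 -35 -34 -33 -31 -30 -29 32
Entomoneis_sp.	-4 -3 -2 -13 -19 -20 -21 -1 23 15 16 -11 -14 -12 -22 -18 -17 -5 -6 -7 -8 -9 -10 -26 -27 -28 -25 -29 30 31 33 34 35 36 37 32 24 42 41 40 39 38
Fistulifera_sp_JPCC_DA0580	-4 -3 -2 -13 -19 -20 -21 -1 23 15 16 -26 -27 -28 10 9 8 7 6 5 17 18 22 12 14 11 25 -38 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 32
Didymosphenia_geminata	-4 -3 -2 -13 -19 -20 -21 -1 23 15 16 -11 -14 -12 -22 -18 -17 -5 -6 -7 -8 -9 -10 -26 -27 -28 25 -38 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 32
Phaeodactylum_tricornutum	-4 -3 -2 -13 -19 -20 -21 -1 23 15 16 -11 -14 -12 -22 -18 -17 -5 -6 -7 -8 -9 -10 -26 -27 -28 25 -38 -39 -40 -41 -42 -24 29 30 31 33 34 35 36 37 32
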