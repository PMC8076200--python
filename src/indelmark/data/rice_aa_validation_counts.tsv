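sample	species	polymorphic_vs_IR24	polymorphic_vs_NB	two_band_count	two_band_percent
Bart_A01	O. barthii	358	174	1	0.211
Bart_A02	O. barthii	365	174	1	0.211
Bart_A03	O. barthii	361	175	1	0.211
Glab_A04	O. glaberrima	363	174	3	0.632
Glab_A05	O. glaberrima	362	176	2	0.421
Glab_A06	O. glaberrima	361	172	2	0.421
Glum_A07	O. glumaepatula	374	179	1	0.211
Glum_A08	O. glumaepatula	369	178	3	0.632
Glum_A09	O. glumaepatula	187	212	18	3.789
Long_A10	O. longistaminata	390	239	60	12.632
Long_A11	O. longistaminata	391	243	60	12.632
Long_A12	O. longistaminata	384	236	44	9.263
Meri_A13	O. meridionalis	306	168	4	0.842
Meri_A14	O. meridionalis	359	203	2	0.421
Meri_A15	O. meridionalis	356	204	6	1.263
Niva_A16	O. nivara	291	126	1	0.211
Niva_A17	O. nivara	189	191	4	0.842
Niva_A18	O. nivara	306	138	4	0.842
Rufi_A19	O. rufipogon	249	163	18	3.789
Rufi_A20	O. rufipogon	189	179	3	0.632
Rufi_A21	O. rufipogon	273	149	36	7.579
Japo_A22	O. sativa japonica	237	43	2	0.421
Japo_A23	O. sativa japonica	256	39	2	0.421
Japo_A24	O. sativa japonica	238	43	2	0.421
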