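ID,Binomial,Class
pop_001,Aves synthetica01,Aves
pop_002,Aves synthetica02,Aves
pop_003,Aves synthetica03,Aves
pop_004,Aves synthetica04,Aves
pop_005,Aves synthetica05,Aves
pop_006,Aves synthetica06,Aves
pop_007,Aves synthetica07,Aves
pop_008,Aves synthetica08,Aves
pop_009,Aves synthetica09,Aves
pop_010,Aves synthetica10,Aves
pop_011,Aves synthetica11,Aves
pop_012,Aves synthetica12,Aves
pop_013,Aves synthetica13,Aves
pop_014,Aves synthetica14,Aves
pop_015,Aves synthetica15,Aves
pop_016,Aves synthetica16,Aves
pop_017,Aves synthetica17,Aves
pop_018,Aves synthetica18,Aves
pop_019,Aves synthetica19,Aves
pop_020,Aves synthetica20,Aves
pop_021,Aves synthetica21,Aves
pop_022,Aves synthetica22,Aves
pop_023,Aves synthetica23,Aves
pop_024,Aves synthetica24,Aves
pop_025,Aves synthetica25,Aves
pop_026,Mammalia syntheticum01,Mammalia
pop_027,Mammalia syntheticum01,Mammalia
pop_028,Mammalia syntheticum02,Mammalia
pop_029,Mammalia syntheticum02,Mammalia
pop_030,Mammalia syntheticum03,Mammalia
pop_031,Mammalia syntheticum03,Mammalia
pop_032,Mammalia syntheticum04,Mammalia
pop_033,Mammalia syntheticum05,Mammalia
pop_034,Reptilia syntheticum01,Reptilia
pop_035,Reptilia syntheticum02,Reptilia
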