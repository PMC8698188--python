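species,scientific_name,wls_model,beta,se,t_value,p_value,pct_change,adj_r2
Great Cormorant,Phalacrocorax carbo,C-NB-GAM,0.050,0.007,-7.046,<0.001,12060,0.78
Black-crowned Night Heron,Nycticorax nycticorax,C-NB-GAM,-0.112,0.068,-1.661,0.111,-47.86,0.07
Little Egret,Egretta garzetta,C-NB-GAM,0.366,0.134,2.745,0.012,100.59,0.22
Grey Heron,Ardea cinerea,C-NB-GAM,0.022,0.008,2.719,0.013,54.76,0.22
Mallard,Anas platyrhynchos,C-ZINB-GAM,0.019,0.003,6.776,<0.001,525.19,0.66
Black Kite,Milvus migrans,C-ZINB-GAM,-0.053,0.022,-2.459,0.022,-54.96,0.18
Common Buzzard,Buteo buteo,C-P-GAM,0.074,0.052,1.416,0.171,50.42,0.04
Common Kestrel,Falco tinnunculus,C-P-GAM,0.083,0.018,4.760,<0.001,239.37,0.49
Common Quail,Coturnix coturnix,C-ZIP-GAM,-0.044,0.030,-1.471,0.155,-46.83,0.05
Common Pheasant,Phasianus colchicus,C-NB-GAM,0.121,0.016,7.596,<0.001,591.31,0.71
Common Moorhen,Gallinula chloropus,C-NB-GAM,-0.008,0.009,-0.819,0.421,-13.83,0
Northern Lapwing,Vanellus vanellus,C-NB-GAM,0.218,0.033,6.514,<0.001,1653.42,0.65
Feral Pigeon,Columba livia domestica,C-ZINB-GAM,0.062,0.079,0.779,0.444,30.28,0
Common Wood Pigeon,Columba palumbus,C-ZIP-GAM,1.213,0.175,6.945,<0.001,1727.33,0.67
Eurasian Collared Dove,Streptopelia decaocto,C-ZINB-GAM,0.415,0.060,6.876,<0.001,196.25,0.67
European Turtle Dove,Streptopelia turtur,C-ZIP-GAM,0.253,0.279,0.907,0.374,22.53,0
Common Cuckoo,Cuculus canorus,C-ZIP-GAM,0.104,0.227,0.458,0.651,5.81,0
Common Swift,Apus apus,C-ZINB-GAM,-1.857,0.583,-3.187,0.004,-50.01,0.29
European Bee-eater,Merops apiaster,C-NB-GAM,0.287,0.045,6.367,<0.001,1325.78,0.63
Eurasian Wryneck,Jynx torquilla,C-ZIP-GAM,-0.484,0.074,-6.557,<0.001,-81.59,0.65
European Green Woodpecker,Picus viridis,C-P-GAM,0.316,0.043,7.314,<0.001,418.48,0.70
Great Spotted Woodpecker,Dendrocopos major,C-P-GAM,0.425,0.034,12.448,<0.001,1530.25,0.87
Eurasian Skylark,Alauda arvensis,C-ZIP-GAM,-0.744,0.087,-8.521,<0.001,-99.65,0.76
Eurasian Crag Martin,Ptyonoprogne rupestris,C-NB-GAM,0.078,0.052,1.498,0.148,64.74,0.05
Barn Swallow,Hirundo rustica,C-ZINB-GAM,-1.788,0.288,-6.209,<0.001,-67.41,0.62
Common House Martin,Delichon urbicum,C-ZINB-GAM,-0.864,0.276,-3.127,0.005,-45.55,0.28
Tree Pipit,Anthus trivialis,C-ZIP-GAM,0.134,0.176,0.761,0.455,14.41,0
Water Pipit,Anthus spinoletta,C-ZINB-GAM,0.019,0.025,0.746,0.463,15.12,0
Western Yellow Wagtail,Motacilla flava,C-ZIP-GAM,-1.057,0.149,-7.073,<0.001,-64.79,0.68
Grey Wagtail,Motacilla cinerea,C-P-GAM,0.003,0.034,0.088,0.931,1.36,0
White Wagtail,Motacilla alba,C-P-GAM,-0.338,0.126,-2.693,0.013,-33.56,0.21
Eurasian Wren,Troglodytes troglodytes,C-ZIP-GAM,-0.054,0.087,-0.626,0.538,-8.91,0
Dunnock,Prunella modularis,C-P-GAM,0.597,0.101,5.923,<0.001,309.03,0.60
European Robin,Erithacus rubecula,C-ZIP-GAM,0.140,0.053,2.640,0.015,35.51,0.21
Common Nightingale,Luscinia megarhynchos,C-ZIP-GAM,-0.356,0.116,-3.055,0.006,-35.32,0.27
Black Redstart,Phoenicurus ochruros,C-ZIP-GAM,0.161,0.021,7.523,<0.001,135.77,0.71
Common Redstart,Phoenicurus phoenicurus,C-ZIP-GAM,0.569,0.121,4.682,<0.001,126.60,0.48
African Stonechat,Saxicola torquatus,C-ZIP-GAM,-0.687,0.143,-4.793,<0.001,-87.83,0.49
Northern Wheatear,Oenanthe oenanthe,C-P-GAM,-0.001,0.006,-0.136,0.893,-3.67,0
Common Blackbird,Turdus merula,C-ZIP-GAM,1.291,0.682,1.894,0.072,25.15,0.10
Song Thrush,Turdus philomelos,C-ZIP-GAM,0.561,0.051,11.026,<0.001,2869.64,0.84
Mistle Thrush,Turdus viscivorus,C-ZIP-GAM,0.439,0.078,5.608,<0.001,468.08,0.57
Cetti's Warbler,Cettia cetti,C-ZIP-GAM,-0.096,0.031,-3.049,0.006,-62.35,0.27
Melodious Warbler,Hippolais polyglotta,C-ZIP-GAM,0.273,0.044,6.154,<0.001,346.07,0.62
Lesser Whitethroat,Curruca curruca,C-ZIP-GAM,0.141,0.042,3.320,0.003,153.05,0.30
Eurasian Blackcap,Sylvia atricapilla,C-ZIP-GAM,0.848,0.387,2.192,0.039,14.50,0.14
Western Bonelli's Warbler,Phylloscopus bonelli,C-ZINB-GAM,0.355,0.110,3.214,0.004,79.62,0.29
Common Chiffchaff,Phylloscopus collybita,C-ZIP-GAM,-0.154,0.053,-2.919,0.008,-40.64,0.25
Goldcrest,Regulus regulus,C-ZIP-GAM,-0.102,0.047,-2.184,0.040,-41.42,0.14
Common Firecrest,Regulus ignicapilla,C-ZIP-GAM,0.363,0.084,4.349,<0.001,309.79,0.44
Spotted Flycatcher,Muscicapa striata,C-P-GAM,1.477,0.209,7.080,<0.001,490.70,0.68
Long-tailed Tit,Aegithalos caudatus,C-P-GAM,0.186,0.049,3.781,0.001,114.79,0.37
Marsh Tit,Poecile palustris,C-ZIP-GAM,0.295,0.049,6.006,<0.001,340.76,0.60
Willow Tit,Poecile montanus,C-ZIP-GAM,0.155,0.068,2.289,0.032,116.63,0.16
European Crested Tit,Lophophanes cristatus,C-ZIP-GAM,0.072,0.020,3.640,0.001,141.11,0.35
Coal Tit,Periparus ater,C-ZIP-GAM,0.046,0.040,1.155,0.261,20.66,0.01
Eurasian Blue Tit,Cyanistes caeruleus,C-ZIP-GAM,0.179,0.071,2.538,0.019,48.78,0.19
Great Tit,Parus major,C-ZIP-GAM,1.615,0.248,6.502,<0.001,104.37,0.64
Eurasian Nuthatch,Sitta europaea,C-ZIP-GAM,0.015,0.009,1.788,0.088,81.84,0.09
Short-toed Treecreeper,Certhia brachydactyla,C-ZIP-GAM,0.160,0.022,7.155,<0.001,998.50,0.70
Eurasian Golden Oriole,Oriolus oriolus,C-ZIP-GAM,0.229,0.067,3.404,0.003,75.75,0.32
Red-backed Shrike,Lanius collurio,C-P-GAM,-0.576,0.112,-5.128,<0.001,-80.13,0.52
Eurasian Jay,Garrulus glandarius,C-P-GAM,0.146,0.020,7.218,<0.001,174.93,0.69
Eurasian Magpie,Pica pica,C-ZIP-GAM,0.279,0.029,9.541,<0.001,753.86,0.80
Carrion Crow,Corvus corone,C-ZIP-GAM,-0.008,0.044,-0.192,0.850,-6.24,0
Hooded Crow,Corvus cornix,C-ZINB-GAM,0.395,0.301,1.309,0.204,13.31,0.03
Common Starling,Sturnus vulgaris,C-ZINB-GAM,-0.261,0.177,-1.473,0.155,-18.55,0.05
Italian Sparrow,Passer italiae,C-ZIP-GAM,-1.902,0.235,-8.077,<0.001,-71.06,0.74
Eurasian Tree Sparrow,Passer montanus,C-ZIP-GAM,-0.272,0.064,-4.253,<0.001,-41.31,0.43
Common Chaffinch,Fringilla coelebs,C-ZIP-GAM,-0.333,0.286,-1.161,0.258,-5.45,0.02
European Serin,Serinus serinus,C-ZIP-GAM,-0.111,0.345,-0.322,0.751,-4.49,0
European Greenfinch,Chloris chloris,C-ZINB-GAM,-2.590,0.338,-7.657,<0.001,-82.00,0.72
European Goldfinch,Carduelis carduelis,C-ZINB-GAM,-2.477,0.297,-8.329,<0.001,-86.89,0.75
Common Linnet,Linaria cannabina,C-ZINB-GAM,0.034,0.044,0.767,0.452,20.60,0
Common Redpoll,Acanthis flammea,C-ZINB-GAM,-0.427,0.247,-1.727,0.098,-42.55,0.08
Eurasian Bullfinch,Pyrrhula pyrrhula,C-ZIP-GAM,0.099,0.063,1.561,0.133,73.22,0.06
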