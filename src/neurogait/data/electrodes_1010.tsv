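name	x	y	z
Fp1	-0.283052179028	0.959079753406	-0.006891339123
Fp2	0.274411062081	0.961559497526	-0.010094638442
F7	-0.755724846622	0.648822209188	-0.088936477681
F3	-0.529501159323	0.700392560365	0.478621754270
Fz	-0.000000000000	0.707477867663	0.706735499863
F4	0.535578043159	0.709146715434	0.458548902164
F8	0.752580973681	0.650875171363	-0.099916912260
FC5	-0.876901509799	0.385997510535	0.286443125197
FC1	-0.360338579956	0.385801263096	0.849301768036
FC2	0.364676571302	0.393655617595	0.843828331522
FC6	0.878703148639	0.390432748444	0.274668974430
T7	-0.991189418793	0.030153281556	-0.128974089194
C3	-0.725192549809	0.008384279275	0.688495075918
Cz	0.000000000000	0.000000000000	1.000000000000
C4	0.736075480695	0.012046444568	0.676792264948
T8	0.989173064728	0.035307587029	-0.142443049376
CP5	-0.891370657748	-0.345469481748	0.293443670381
CP1	-0.358660632169	-0.368683552183	0.857575063351
CP2	0.376185135405	-0.369556124937	0.849654644207
CP6	0.896811231952	-0.341231419041	0.281586102114
TP9	-0.842218408425	-0.239902054813	-0.482820004357
TP10	0.829032781368	-0.252935826662	-0.498726493188
P7	-0.796001081615	-0.597261357138	-0.098291145775
P3	-0.551556867311	-0.670008169671	0.496864241717
Pz	-0.004468325795	-0.685157393548	0.728381342520
P4	0.556579319897	-0.667976797760	0.493990342333
P8	0.787295819878	-0.606875900104	-0.108935457389
POz	-0.008433299824	-0.907374167887	0.420239216287
O1	-0.307009228142	-0.951618387033	-0.012952964780
Oz	-0.011948412806	-0.999045749357	0.042009833637
O2	0.287322606343	-0.957690291120	-0.016583913239
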