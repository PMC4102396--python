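name,value
K_EC_ELF4,0.3504850701596181
K_EC_GI,0.2262526807057629
K_EC_LUX,0.32946757016539047
K_EC_PRR5,0.22112082661637292
K_EC_PRR7,0.23458689673567948
K_EC_PRR9,0.2491699550578382
K_EC_TOC1,0.11088173917519098
K_ELF3,0.6494692851322479
K_LC_ELF3,0.4608959212399651
K_LC_ELF4,0.3218530139304851
K_LC_GI,0.1800984633775231
K_LC_LUX,0.43919400848463863
K_LC_PRR5,1.0458957345551703
K_LC_PRR7,1.5076634067982224
K_LC_TOC1,0.609851974543092
K_LUXNOX,1.0621605161878975
K_PRR5_CCA1,0.6566825345226665
K_PRR5_LHY,0.5108125467167131
K_PRR5_PRR7,0.3847100619277315
K_PRR5_PRR9,0.2906331663227377
K_PRR5_RVE8,0.5291502694186712
K_PRR7_CCA1,0.7331573643428617
K_PRR7_LHY,0.9297146675349647
K_PRR7_NOX,0.4725057845131785
K_PRR7_RVE8,0.42822255023658085
K_PRR9_CCA1,1.1755354910478542
K_PRR9_LHY,0.7417195790864896
K_PRR9_RVE8,0.36868220843209853
K_RVE8_ELF4,0.3869725479985453
K_RVE8_GI,0.3879346939553115
K_RVE8_LUX,0.39078822815541153
K_RVE8_PRR5,0.3985446790660068
K_RVE8_PRR9,0.555287864788347
K_RVE8_TOC1,0.2766499051450776
K_TOC1_CCA1,0.7709395099500009
K_TOC1_LHY,0.5897583465680917
K_TOC1_PRR5,0.42171879478875646
K_TOC1_PRR7,0.7110668180972651
K_TOC1_PRR9,0.41219801490644303
K_TOC1_TOC1,0.7394129505199866
a_PRR9,3.1120387615183023
c_E3,0.13739397215159968
c_NOX,0.2701057715997487
d_E34,0.5257770605801961
d_ZG,0.21960358530612248
d_ZTL,0.18300298775510207
dc_COP1,0.21960358530612248
dm_CCA1,0.6588107559183675
dm_ELF3,0.36600597551020414
dm_ELF4,0.5124083657142857
dm_GI,0.5124083657142857
dm_LHY,0.6588107559183675
dm_LUX,0.5124083657142857
dm_NOX,0.4642120658070849
dm_PRR5,0.43920717061224496
dm_PRR7,0.43920717061224496
dm_PRR9,0.5856095608163266
dm_RVE8,0.36600597551020414
dm_TOC1,0.43920717061224496
dn_COP1,0.2928047804081633
dp_CCA1,0.43920717061224496
dp_ELF3,0.21960358530612248
dp_ELF4,0.5970725345738953
dp_GI,0.2928047804081633
dp_LHY,0.43920717061224496
dp_LUX,0.47856412210412835
dp_NOX,0.2928047804081633
dp_PRR5,0.24373246599296738
dp_PRR7,0.1779866869988928
dp_PRR9,0.2804230354794038
dp_RVE8,0.2868138089812704
dp_TOC1,0.32064069762632375
ka_E34,1.4640239020408166
ka_ZG,1.4640239020408166
kd_ZG,1.4640239020408166
m_COP1_ELF3c,0.5856095608163266
m_COP1_ELF3n,0.5856095608163266
m_COP1_GIn,0.5856095608163266
m_ZTL_PRR5,2.107636650924202
m_ZTL_TOC1,1.358829198480379
p_CCA1,0.8784143412244899
p_COP1,0.36600597551020414
p_ELF3,0.7320119510204083
p_ELF4,0.7320119510204083
p_GI,0.7320119510204083
p_LHY,0.8784143412244899
p_LUX,0.7320119510204083
p_NOX,0.5856095608163266
p_PRR5,0.7320119510204083
p_PRR7,0.7320119510204083
p_PRR9,0.7320119510204083
p_RVE8,0.5856095608163266
p_TOC1,0.7320119510204083
p_ZTL,0.1712011792204467
s_RVE8_ELF4,0.5531097580750658
s_RVE8_GI,1.3484822822694253
s_RVE8_LUX,1.5359518743353666
s_RVE8_PRR5,1.1495988434485227
s_RVE8_PRR9,1.431152647261478
s_RVE8_TOC1,1.392288657699011
t_CCA1,1.0980179265306125
t_COP1,0.5856095608163266
t_ELF3,0.5856095608163266
t_GI,0.7320119510204083
t_LHY,1.0980179265306125
t_PRR5,0.7320119510204083
t_TOC1,0.7320119510204083
v_CCA1,3.6600597551020417
v_ELF3,1.4640239020408166
v_ELF4,2.196035853061225
v_GI,2.196035853061225
v_LHY,3.6600597551020417
v_LUX,2.196035853061225
v_NOX,1.3867669323678347
v_PRR5,2.196035853061225
v_PRR7,2.196035853061225
v_PRR9,1.7807035530549193
v_RVE8,1.4640239020408166
v_TOC1,2.196035853061225
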