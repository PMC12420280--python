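residue	PC1	PC2	PC3	PC4	PC5	PC6	PC7	PC8	PC9	PC10	PC11	PC12	PC13	PC14	PC15
A	19.90443273	-5.614521609	-0.3123042464	4.81585478	-1.126162182	-1.6260065	4.206806886	1.125746955	-0.7806506285	-0.7359507317	-0.4027859294	-0.3271960267	1.237357687	-0.94441577	-0.4102486559
C	-13.24985963	-0.6157314794	-11.35315494	2.3264975	13.9965364	2.733156944	8.695687541	-3.381693725	0.4879723719	-0.2489631739	0.4301439269	1.841027751	-0.3136058197	0.04588662951	0.6184435696
D	12.89570182	-2.090897586	6.27466355	18.4206614	10.26690959	-8.014059191	-5.216489972	-1.024148222	-0.7526681267	0.9658981505	-0.9306543437	0.029543248	-1.193609636	0.1285452482	0.120577881
E	-4.669968188	15.50907038	0.2407740878	-0.8245793638	-10.06674386	4.156173913	-3.087183963	-1.210428732	-0.4665610633	-0.03427760339	1.663327242	1.051016372	-1.626108688	0.09379874491	-1.663320097
F	2.334850749	2.129371811	6.309425872	-9.458948513	9.979995611	-3.279735257	0.1087887142	1.881039218	-1.624375188	1.872561456	0.8492520682	0.9598205844	0.9038608446	-0.5990032718	-0.6565324229
G	11.90607582	-0.0771853515	-8.201025035	-9.822168903	10.26945648	6.386101448	0.2573157908	4.61643862	0.3093376619	-0.4313178458	0.484914022	-1.206449214	-0.5181957618	1.475485568	0.1318483468
H	8.669596007	19.99114934	-5.128113683	4.732851113	-1.45312512	-7.224136784	6.460985152	0.6437487485	0.9138051637	-1.365236522	-0.6913387225	-0.7131244006	-1.030553683	-0.3260220482	-0.1547160413
I	-8.097165506	-1.846171874	17.01792289	2.109845554	-0.1771198827	7.559323152	-0.343474857	1.403137388	1.499246737	0.4593292377	0.7476144693	-0.3707498486	-0.7576540999	-1.514842557	2.042114616
K	1.177856241	-17.36072982	-6.229429887	6.25307492	-6.223510215	4.253623401	2.247641682	-2.42319621	0.4758380469	0.4544586335	0.7044018149	-1.324607387	0.8881750011	-1.137976195	-1.039903452
L	32.04788651	-17.81642728	5.861710706	-3.422113935	-2.727317809	5.744817305	0.7475875135	-2.42634198	0.1253646645	-0.09865214089	0.4575169734	0.257116277	-0.8728924442	1.063050772	-0.06993952208
M	-22.95094788	-17.02464383	7.366477608	-3.080954151	0.9278595535	-6.069706358	-3.977624244	-2.168187497	-0.06580868174	-1.390502608	-0.1206031355	-0.4492134242	0.3859283569	1.781466971	0.1439793279
N	-8.47748483	-11.90075613	9.168442559	-9.457896075	-4.85669181	-5.657337026	1.723209223	2.804806588	0.2294043934	-0.9509981633	-1.311583164	1.072245812	-1.041068267	-0.8435556596	-0.89553659
P	3.825867649	13.11866512	3.25681399	9.138351226	-2.574397357	10.68453771	-5.578085789	1.12314858	0.9236087652	-0.4237991304	-1.364164594	1.570246026	1.709955242	0.8591791614	-0.2198515115
Q	-16.29688504	8.013968193	1.702592378	1.149747256	-7.515163395	4.337398291	6.480975176	-0.2462257357	-1.118247956	2.18492996	-1.390767478	-1.363066687	-0.4615257284	1.244536364	0.1100983513
R	0.2680259845	14.74171984	10.81845624	-4.99762304	-0.4214426136	0.9849442651	3.44200827	-2.058468059	-1.913855194	-1.643488874	0.3498531817	-0.476754267	1.170027252	-0.2377052433	0.7860999814
S	2.226291596	-5.51324917	-6.006074988	-9.05760876	-5.693417511	-4.836988417	2.555303878	-0.2452137829	1.536241622	1.374010955	-1.035915937	0.8854999913	0.8065576864	0.07785776522	0.2194413807
T	-9.737826402	-7.690150331	-8.687657741	13.69129776	-8.68758227	-6.308090915	0.347302857	4.185034681	-0.5400625748	-0.1070753096	1.82614154	0.5242489645	0.4586465435	0.647120417	0.8318056298
V	11.66725394	10.91624037	-10.57756176	-10.70446795	-6.573033778	-7.35878086	-8.045640992	-2.300527862	0.1026652403	0.4667530041	0.1721403197	-0.1415589256	0.06611686267	-0.2984281481	1.627080684
W	-9.803959607	10.33948274	3.871923075	-0.2998900613	8.804839423	-4.335602657	-3.608851754	-0.5990727592	1.975639605	0.2823748772	0.7745342513	-1.373620864	0.7632717812	-0.106871325	-1.471258776
Y	-13.63974197	-7.209203329	-15.39388067	-1.511930749	3.850110742	7.870367539	-7.416261113	0.3004037858	-1.316894857	-0.6300541707	-1.212026505	-0.4444239814	-0.5746831293	-1.408107422	-0.05018269989
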