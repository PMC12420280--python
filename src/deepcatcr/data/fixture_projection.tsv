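residue	PC1	PC2	PC3	PC4	PC5	PC6	PC7	PC8	PC9	PC10	PC11	PC12	PC13	PC14	PC15
A	-0.8475155146	0.0685425328	-1.250925973	-1.583636691	0.6324575844	-0.469675389	1.186915308	0.3747215669	-2.141918402	-0.4220163416	-1.109587527	-0.3624772545	0.08937309554	0.7941812754	-1.526650758
C	-1.28148383	-0.5202150248	-1.231869436	-1.031033004	0.3793659491	-1.753145109	-1.391378621	2.288082758	-1.886944862	-1.223845298	-0.02568825457	-0.8569108057	0.3114498749	-0.2164200006	0.8194756923
D	-0.2257356972	1.07072276	-0.06013414532	-0.2423719698	-0.444205497	0.06067046202	0.5485719489	-0.1298805201	0.7379521479	0.5626378774	0.2187569525	-0.1951774181	-0.9938349614	-1.068153951	0.7726736027
E	1.190088173	-1.841031053	2.015262064	-0.3435903635	-0.7192363365	-0.2160086498	-1.787536224	-1.260879898	0.4560646003	-0.4285965628	0.5171768371	-0.1663828959	1.113352068	-1.248592391	-0.1616436782
F	-1.009776079	-0.3773994103	0.5265412216	0.7626253008	-0.128332121	0.3880989292	-1.59330663	-0.7642496058	0.7747179668	0.8018496938	-1.283089703	0.3348221716	-1.775554178	1.192331795	-1.035014346
G	-0.6295911914	0.6847123568	0.4713376023	-1.042331022	-0.3620269725	1.427416421	0.1436668609	-1.637157611	2.074193996	0.3305588437	-0.8293227867	-2.376925777	-1.394814904	-1.079622629	-0.3521927263
H	-1.33446099	-0.1786443481	-0.2451324086	2.494579816	1.123530643	-0.0476530222	-0.7738236163	-2.503842692	-2.177208828	0.1163601927	1.300965522	1.096313128	-1.008861547	-0.3800390434	0.2273378393
I	-1.315217779	0.6651482857	0.3626774651	0.9399033082	0.9761742391	0.9197262137	-0.9096990349	-1.742638383	0.4102702392	-1.083997822	-1.0253036	0.2887247974	-0.3049537853	0.4898148946	1.835632628
K	-0.2565019904	-1.00560464	0.1089957773	0.07044201398	1.793279982	0.7855016585	-0.02454523673	-0.6194462802	1.291862951	-0.739410233	-1.406564193	-2.324374745	0.9134085152	-0.07290688043	0.6034286092
L	-0.7492200196	-1.084363233	-0.5927536606	-0.3285963177	-1.211158413	1.458271637	1.137394521	2.620287486	-0.05256145308	0.4738949837	0.9236608297	0.1699103841	0.9893730998	-0.166195441	-1.081005855
M	-0.1776043517	0.4928858823	0.2836383279	-1.539140918	-0.9314923683	0.3244018357	-0.4581671677	-0.03560700671	0.6939022067	-1.366514102	0.04455863032	-0.3162077505	-0.6247177768	0.2823954636	-1.763456919
N	0.8308089197	-0.4898418393	0.07848253101	-0.1476711133	-0.6254038766	0.6442766047	-1.402067527	-0.5321609462	-0.1920344902	0.1887288565	1.182424357	0.4915355801	1.308705086	0.3441813134	-1.673808134
P	-0.6591105856	0.7657759514	0.9816434558	0.06938926205	-0.4440580479	-0.1465829508	-0.3454184391	-0.3709538326	0.8077210456	-1.253944666	-0.2411710908	0.4697619058	-0.7370258606	0.7589191273	-0.8598907242
Q	-1.492251879	-1.198629483	1.486918736	2.442245684	0.7432922282	-0.5900444141	-0.6804353285	0.1853572346	0.6315452592	0.7204408474	-0.6358938304	0.2349233454	-0.01447151947	0.1934579953	-1.499835269
R	0.1597168063	0.5446074043	-0.1308037913	-0.2356858833	-0.5845076327	0.1121083144	-2.439036675	0.1784384434	-0.04556626672	1.516967379	0.4218735072	0.5530997023	2.575205296	-0.7009045206	1.027983406
S	-1.24848101	-1.673911652	-0.754629889	0.9606162891	-2.271872584	1.293727599	-1.445709644	-0.09352597716	0.7047567516	2.355197559	-0.2953629219	-1.255353739	0.614215455	-0.2889555583	1.346013972
T	0.296197142	1.194230606	-0.2012058769	-2.556711279	-1.089205669	-0.7568599267	0.9762125361	0.4783766245	0.4173598115	-0.5381733784	0.4066358937	0.9631706291	-0.4246678767	0.2113095858	-2.33898281
V	0.1159796271	-1.005251168	-0.1585947542	-0.1033284193	0.06996861836	-1.030134566	0.1404325841	-0.1961602956	-0.326024847	1.566146641	-0.7326834762	-1.399037153	-0.6334096189	0.817522134	-1.30124206
W	1.830427215	0.6264492977	-0.5627882278	0.5472615992	1.190955497	-0.4514975361	-0.8676188215	-0.2182408329	0.1032141372	-0.5264055167	-0.1366116598	-0.213214865	0.3239262981	0.5269560423	1.717652402
Y	0.5383123469	-0.5593364908	0.2777161567	-1.041017528	-0.2918905436	-0.3987068126	1.153401273	0.02189875424	-0.5964397554	1.004820314	1.350951644	0.4153914713	-0.9535824696	-1.995783905	0.2940293525
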