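##fileformat=VCFv4.2
##contig=<ID=1A>
##contig=<ID=1B>
##contig=<ID=2A>
##contig=<ID=2B>
##contig=<ID=3A>
##contig=<ID=3B>
##contig=<ID=4A>
##contig=<ID=4B>
##contig=<ID=5A>
##contig=<ID=5B>
##contig=<ID=6A>
##contig=<ID=6B>
##contig=<ID=7A>
##contig=<ID=7B>
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand score">
##INFO=<ID=MDP,Number=1,Type=Float,Description="Mean sample depth">
##INFO=<ID=NALL,Number=1,Type=Integer,Description="Observed allele count">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	grpA_001	grpA_002	grpA_003	grpA_004	grpB_001	grpB_002	grpB_003	grpB_004	grpC_001	grpC_002	grpC_003
1A	7215636	.	G	C	959.963	.	QD=30.7471;FS=6.439;MDP=28.8212	GT	0/0	0/0	0/0	1/1	0/1	0/0	./.	0/0	0/1	0/0	0/0
1A	287889441	.	C	T	426.878	.	QD=1.1872;FS=10.1089;MDP=31.3139	GT	0/0	0/0	0/0	0/0	./.	0/0	0/0	0/0	0/0	0/0	0/0
1A	568024120	.	G	A	695.612	.	QD=18.3108;FS=7.1676;MDP=39.6854	GT	0/0	0/0	0/0	0/0	1/1	1/1	1/1	1/1	1/1	1/1	1/1
1A	592829878	.	G	A	514.577	.	QD=39.9293;FS=1.0222;MDP=37.6285	GT	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/1	0/1	0/0	0/0
1B	29891630	.	C	T	862.366	.	QD=38.0192;FS=7.6248;MDP=20.2868	GT	0/0	1/1	./.	0/0	0/0	0/1	0/0	./.	0/0	0/0	0/0
1B	37645757	.	G	T	275.807	.	QD=37.4021;FS=9.0852;MDP=31.3379	GT	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0
1B	169428406	.	G	C	51.0894	.	QD=29.9956;FS=321.724;MDP=18.5199	GT	0/1	0/0	0/0	0/0	0/0	./.	0/0	0/1	0/0	0/0	0/0
2A	167231878	.	G	C	778.947	.	QD=10.5849;FS=9.6159;MDP=34.0449	GT	0/1	./.	0/0	0/1	0/0	0/1	0/1	./.	0/0	0/0	0/1
2A	186134987	.	C	T	130.838	.	QD=29.914;FS=4.6266;MDP=19.0787	GT	1/1	0/0	0/1	0/0	0/1	0/1	0/1	0/0	0/1	0/0	0/1
2A	723730459	.	C	G	606.119	.	QD=14.4714;FS=1.4444;MDP=25.0129	GT	1/1	1/1	1/1	1/1	0/0	0/0	0/0	0/0	0/0	./.	./.
2A	727260957	.	C	T	515.919	.	QD=24.9395;FS=4.462;MDP=16.0111	GT	0/1	0/0	0/1	0/1	0/1	1/1	0/0	0/0	0/1	0/1	0/0
2B	73320478	.	T	C	163.678	.	QD=16.0974;FS=1.2053;MDP=10.8769	GT	0/1	0/0	0/0	./.	0/0	0/0	0/0	0/1	0/0	0/0	0/0
2B	166849299	.	A	G	13.4579	.	QD=15.0301;FS=25.1938;MDP=24.1684	GT	0/0	1/1	1/1	1/1	1/1	./.	./.	1/1	0/0	0/0	0/0
2B	528471461	.	C	T	901.471	.	QD=10.6531;FS=5.58;MDP=15.302	GT	1/1	0/0	0/1	0/1	./.	0/1	1/1	0/0	0/0	0/0	0/0
2B	649517653	.	G	T	778.649	.	QD=38.3911;FS=5.285;MDP=10.3136	GT	1/1	./.	0/0	0/0	0/0	./.	0/0	./.	0/0	0/0	0/0
3A	86771255	.	T	G	882.114	.	QD=21.2705;FS=11.983;MDP=18.1586	GT	0/1	0/0	0/1	0/0	0/0	./.	0/0	./.	0/0	0/0	0/0
3B	137977983	.	C	T	469.646	.	QD=35.4879;FS=3.556;MDP=17.3827	GT	0/1	./.	./.	0/0	0/0	1/1	0/1	0/0	0/0	0/0	0/0
3B	625759261	.	C	T	210.626	.	QD=38.2191;FS=2.1009;MDP=17.8603	GT	0/0	0/0	0/0	0/0	0/0	0/1	0/1	0/0	./.	0/0	0/0
4A	165284862	.	G	A	737.661	.	QD=19.1605;FS=1.8518;MDP=31.0418	GT	0/0	0/0	0/0	0/0	1/1	1/1	1/1	1/1	./.	1/1	./.
4A	212430730	.	A	G	441.78	.	QD=18.4347;FS=4.8154;MDP=25.7811	GT	1/1	1/1	1/1	1/1	1/1	1/1	1/1	./.	0/0	0/0	./.
4A	216903315	.	T	C	919.055	.	QD=23.8978;FS=19.3788;MDP=39.5824	GT	1/1	./.	1/1	1/1	0/0	0/0	0/0	./.	1/1	1/1	1/1
4A	280817118	.	G	T	406.292	.	QD=25.4696;FS=4.8454;MDP=28.7439	GT	./.	0/0	0/0	0/0	0/0	0/0	0/0	./.	1/1	1/1	1/1
4A	452362698	.	T	C	588.841	.	QD=32.2665;FS=1.7312;MDP=23.7685	GT	./.	1/1	0/1	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0
4A	561017617	.	C	T	339.251	.	QD=14.9642;FS=1.0679;MDP=15.8064	GT	./.	./.	0/0	0/0	0/0	0/0	0/0	0/0	0/1	0/0	./.
4A	600179773	.	A	G	679.343	.	QD=25.7066;FS=7.592;MDP=22.0898	GT	0/0	0/0	0/0	0/0	1/1	1/1	./.	1/1	0/0	0/0	0/0
4A	652126431	.	G	A	127.233	.	QD=31.4322;FS=1.2835;MDP=17.5249	GT	0/1	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0
4B	179214749	.	C	A	421.151	.	QD=18.3069;FS=1.3265;MDP=27.9367	GT	0/1	./.	0/0	0/1	1/1	0/1	0/1	0/0	./.	0/0	0/0
4B	301747026	.	A	G	803.953	.	QD=20.119;FS=11.9967;MDP=2.0309	GT	0/1	0/0	./.	0/1	0/0	0/0	0/0	0/0	0/0	./.	0/0
4B	517873151	.	C	T	737.577	.	QD=39.7129;FS=0.0784;MDP=12.877	GT	0/0	1/1	0/0	0/0	0/1	0/0	1/1	0/0	0/0	./.	0/0
4B	624068000	.	T	C	379.15	.	QD=23.6752;FS=2.048;MDP=36.5136	GT	0/1	0/1	./.	0/1	0/1	0/1	0/0	0/0	0/0	0/0	0/0
5A	2333637	.	T	C	466.059	.	QD=15.5054;FS=6.5589;MDP=33.0345	GT	1/1	1/1	1/1	1/1	0/0	0/0	0/0	0/0	1/1	1/1	./.
5A	102487664	.	G	A	942.088	.	QD=30.2063;FS=1.7957;MDP=8.6436	GT	0/1	0/1	0/0	0/0	0/0	0/0	0/0	0/1	0/0	./.	0/0
5A	169819127	.	C	G	56.4201	.	QD=21.3179;FS=1.7738;MDP=39.1485	GT	1/1	1/1	1/1	./.	0/0	0/0	0/0	0/0	0/0	0/0	0/0
5A	262401506	.	T	C	809.306	.	QD=39.4078;FS=0.6048;MDP=19.3224	GT	0/0	0/1	0/0	0/1	0/1	0/1	0/0	0/0	0/0	0/1	0/1
5A	346020217	.	G	A	297.66	.	QD=31.8082;FS=0.0353;MDP=11.3461	GT	0/0	0/0	0/0	0/0	1/1	1/1	1/1	1/1	1/1	1/1	1/1
5A	494414717	.	A	G	408.989	.	QD=14.001;FS=2.1597;MDP=8.209	GT	./.	0/0	0/0	0/0	0/0	0/0	./.	0/0	1/1	1/1	1/1
5A	590395748	.	T	A	184.061	.	QD=23.5467;FS=7.8115;MDP=23.7073	GT	0/0	0/1	./.	0/1	0/0	0/1	1/1	0/0	0/1	0/0	1/1
5B	453168950	.	G	A	253.603	.	QD=16.3919;FS=26.8523;MDP=28.9544	GT	0/1	0/0	0/1	0/1	0/0	0/1	0/0	0/0	0/0	0/0	0/0
5B	462352722	.	C	T	400.343	.	QD=25.6427;FS=0.1428;MDP=20.9688	GT	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/1	0/0	0/0	0/0
5B	500130458	.	G	A	554.257	.	QD=13.2288;FS=2.588;MDP=32.8545	GT	0/0	0/1	1/1	0/1	0/1	0/1	1/1	0/0	0/0	./.	0/0
5B	682426178	.	A	G	71.0062	.	QD=38.8668;FS=34.175;MDP=32.192	GT	1/1	0/1	0/1	0/1	0/1	0/1	1/1	0/0	./.	0/0	0/0
6A	48644488	.	A	G	767.139	.	QD=15.3921;FS=370.971;MDP=10.1647	GT	1/1	0/1	0/1	1/1	0/1	0/1	1/1	0/1	0/1	0/0	0/1
6A	134362007	.	A	C	753.116	.	QD=33.3035;FS=2.3422;MDP=30.2109	GT	0/0	0/0	1/1	0/1	0/1	0/1	0/0	1/1	0/1	0/0	1/1
6A	457315064	.	C	A	656.614	.	QD=23.0352;FS=4.4755;MDP=8.1117	GT	0/0	./.	0/0	0/0	0/0	./.	0/0	0/0	1/1	1/1	./.
6A	467957530	.	G	A	539.862	.	QD=12.0246;FS=0.5091;MDP=19.2431	GT	1/1	1/1	1/1	1/1	0/0	0/0	0/0	0/0	1/1	1/1	1/1
6B	71908356	.	C	A	229.345	.	QD=11.4647;FS=0.4372;MDP=27.6367	GT	0/1	0/0	0/1	0/0	0/1	0/0	./.	0/1	0/0	0/0	./.
6B	147840213	.	C	T	343.233	.	QD=15.3746;FS=6.4538;MDP=12.3084	GT	0/0	0/0	0/0	0/0	0/0	0/0	0/1	0/1	./.	0/0	0/0
6B	171530940	.	A	G	909.774	.	QD=29.6612;FS=1.1254;MDP=33.6326	GT	0/1	0/0	0/1	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0
6B	349778101	.	C	G	577.903	.	QD=11.7106;FS=0.1811;MDP=33.6146	GT	0/0	0/0	0/1	0/0	0/0	0/1	0/1	1/1	0/0	0/0	0/0
6B	402594802	.	G	C	807.997	.	QD=23.641;FS=7.8662;MDP=14.7707	GT	0/1	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0
6B	553385078	.	A	C	724.592	.	QD=33.2782;FS=6.1735;MDP=29.384	GT	0/1	0/1	1/1	./.	./.	0/1	0/0	0/0	0/0	0/0	0/0
7A	53652828	.	T	C	472.905	.	QD=2.1356;FS=1.7308;MDP=18.6789	GT	1/1	1/1	1/1	1/1	1/1	1/1	1/1	1/1	0/0	0/0	0/0
7A	116851891	.	G	C	90.8529	.	QD=25.4705;FS=2.9928;MDP=29.7132	GT	1/1	0/1	0/1	0/0	0/1	0/0	0/1	0/1	0/1	0/0	1/1
7A	607716096	.	G	A	147.591	.	QD=16.1636;FS=18.4558;MDP=19.0864	GT	0/0	0/0	0/0	./.	1/1	1/1	1/1	1/1	0/0	0/0	./.
7A	720212280	.	C	T	597.331	.	QD=24.2387;FS=23.312;MDP=30.088	GT	0/1	0/0	0/1	0/0	0/1	0/0	0/1	1/1	1/1	0/0	0/1
7B	170607373	.	C	T	432.294	.	QD=21.7638;FS=4.8816;MDP=39.0007	GT	0/0	./.	0/1	0/1	0/1	0/0	0/1	0/1	0/0	0/0	0/0
7B	287125859	.	G	A	454.373	.	QD=16.9071;FS=6.7095;MDP=9.8305	GT	0/1	./.	1/1	0/1	0/0	0/0	0/0	0/1	0/0	0/0	0/0
7B	432450602	.	C	G	486.834	.	QD=15.372;FS=1.7251;MDP=27.1322	GT	1/1	0/1	1/1	0/1	0/1	1/1	0/0	0/0	0/0	0/0	0/0
7B	609187119	.	T	C	250.47	.	QD=12.1148;FS=0.1386;MDP=39.8806	GT	0/1	./.	./.	0/0	0/0	0/1	./.	0/0	0/0	0/0	0/0
7B	736601887	.	G	A	93.2908	.	QD=39.4029;FS=2.008;MDP=32.9497	GT	0/0	0/1	./.	0/1	0/0	0/0	0/0	0/0	0/0	0/0	./.
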