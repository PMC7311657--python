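chrom	pos	subgenome	ref	alt	sub_class	is_diagnostic	contrast_id	high_side	freq_grpA	freq_grpB	freq_grpC	fail_qual	fail_qd	fail_fs	fail_depth	fail_biallelic
1A	7215636	A	G	C	G/C	False			0.280123	0.280123	0.280123	False	False	False	False	False
1A	287889441	A	C	T	C/T	False			0.152755	0.152755	0.152755	False	True	False	False	False
1A	568024120	A	G	A	G/A	True	grpA-vs-rest	b	0.0	1.0	1.0	False	False	False	False	False
1A	592829878	A	G	A	G/A	False			0.111207	0.111207	0.111207	False	False	False	False	False
1B	29891630	B	C	T	C/T	False			0.383921	0.383921	0.383921	False	False	False	False	False
1B	37645757	B	G	T	G/T	False			0.116788	0.116788	0.116788	False	False	False	False	False
1B	169428406	B	G	C	G/C	False			0.192865	0.192865	0.192865	False	False	True	False	False
2A	167231878	A	G	C	G/C	False			0.184385	0.184385	0.184385	False	False	False	False	False
2A	186134987	A	C	T	C/T	False			0.354622	0.354622	0.354622	False	False	False	False	False
2A	723730459	A	C	G	C/G	True	grpA-vs-rest	a	1.0	0.0	0.0	False	False	False	False	False
2A	727260957	A	C	T	C/T	False			0.433517	0.433517	0.433517	False	False	False	False	False
2B	73320478	B	T	C	T/C	False			0.180659	0.180659	0.180659	False	False	False	False	False
2B	166849299	B	A	G	A/G	False			0.467218	0.467218	0.467218	True	False	False	False	False
2B	528471461	B	C	T	C/T	False			0.497586	0.497586	0.497586	False	False	False	False	False
2B	649517653	B	G	T	G/T	False			0.095384	0.095384	0.095384	False	False	False	False	False
3A	86771255	A	T	G	T/G	False			0.204131	0.204131	0.204131	False	False	False	False	False
3B	137977983	B	C	T	C/T	False			0.192568	0.192568	0.192568	False	False	False	False	False
3B	625759261	B	C	T	C/T	False			0.174021	0.174021	0.174021	False	False	False	False	False
4A	165284862	A	G	A	G/A	True	grpA-vs-rest	b	0.0	1.0	1.0	False	False	False	False	False
4A	212430730	A	A	G	A/G	True	grpC-vs-rest	b	1.0	1.0	0.0	False	False	False	False	False
4A	216903315	A	T	C	T/C	True	grpB-vs-rest	b	1.0	0.0	1.0	False	False	False	False	False
4A	280817118	A	G	T	G/T	True	grpC-vs-rest	a	0.0	0.0	1.0	False	False	False	False	False
4A	452362698	A	T	C	T/C	False			0.200944	0.200944	0.200944	False	False	False	False	False
4A	561017617	A	C	T	C/T	False			0.078443	0.078443	0.078443	False	False	False	False	False
4A	600179773	A	A	G	A/G	True	grpB-vs-rest	a	0.0	1.0	0.0	False	False	False	False	False
4A	652126431	A	G	A	G/A	False			0.051646	0.051646	0.051646	False	False	False	False	False
4B	179214749	B	C	A	C/A	False			0.440738	0.440738	0.440738	False	False	False	False	False
4B	301747026	B	A	G	A/G	False			0.231825	0.231825	0.231825	False	False	False	True	False
4B	517873151	B	C	T	C/T	False			0.322221	0.322221	0.322221	False	False	False	False	False
4B	624068000	B	T	C	T/C	False			0.428759	0.428759	0.428759	False	False	False	False	False
5A	2333637	A	T	C	T/C	True	grpB-vs-rest	b	1.0	0.0	1.0	False	False	False	False	False
5A	102487664	A	G	A	G/A	False			0.11736	0.11736	0.11736	False	False	False	False	False
5A	169819127	A	C	G	C/G	True	grpA-vs-rest	a	1.0	0.0	0.0	False	False	False	False	False
5A	262401506	A	T	C	T/C	False			0.238999	0.238999	0.238999	False	False	False	False	False
5A	346020217	A	G	A	G/A	True	grpA-vs-rest	b	0.0	1.0	1.0	False	False	False	False	False
5A	494414717	A	A	G	A/G	True	grpC-vs-rest	a	0.0	0.0	1.0	False	False	False	False	False
5A	590395748	A	T	A	T/A	False			0.217747	0.217747	0.217747	False	False	False	False	False
5B	453168950	B	G	A	G/A	False			0.266807	0.266807	0.266807	False	False	False	False	False
5B	462352722	B	C	T	C/T	False			0.145233	0.145233	0.145233	False	False	False	False	False
5B	500130458	B	G	A	G/A	False			0.225591	0.225591	0.225591	False	False	False	False	False
5B	682426178	B	A	G	A/G	False			0.446669	0.446669	0.446669	False	False	False	False	False
6A	48644488	A	A	G	A/G	False			0.448212	0.448212	0.448212	False	False	True	False	False
6A	134362007	A	A	C	A/C	False			0.428491	0.428491	0.428491	False	False	False	False	False
6A	457315064	A	C	A	C/A	True	grpC-vs-rest	a	0.0	0.0	1.0	False	False	False	False	False
6A	467957530	A	G	A	G/A	True	grpB-vs-rest	b	1.0	0.0	1.0	False	False	False	False	False
6B	71908356	B	C	A	C/A	False			0.259866	0.259866	0.259866	False	False	False	False	False
6B	147840213	B	C	T	C/T	False			0.172669	0.172669	0.172669	False	False	False	False	False
6B	171530940	B	A	G	A/G	False			0.265714	0.265714	0.265714	False	False	False	False	False
6B	349778101	B	C	G	C/G	False			0.171155	0.171155	0.171155	False	False	False	False	False
6B	402594802	B	G	C	G/C	False			0.050464	0.050464	0.050464	False	False	False	False	False
6B	553385078	B	A	C	A/C	False			0.28624	0.28624	0.28624	False	False	False	False	False
7A	53652828	A	T	C	T/C	True	grpC-vs-rest	b	1.0	1.0	0.0	False	True	False	False	False
7A	116851891	A	G	C	G/C	False			0.496703	0.496703	0.496703	False	False	False	False	False
7A	607716096	A	G	A	G/A	True	grpB-vs-rest	a	0.0	1.0	0.0	False	False	False	False	False
7A	720212280	A	C	T	C/T	False			0.490146	0.490146	0.490146	False	False	False	False	False
7B	170607373	B	C	T	C/T	False			0.208433	0.208433	0.208433	False	False	False	False	False
7B	287125859	B	G	A	G/A	False			0.257026	0.257026	0.257026	False	False	False	False	False
7B	432450602	B	C	G	C/G	False			0.457628	0.457628	0.457628	False	False	False	False	False
7B	609187119	B	T	C	T/C	False			0.324816	0.324816	0.324816	False	False	False	False	False
7B	736601887	B	G	A	G/A	False			0.189111	0.189111	0.189111	False	False	False	False	False
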