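name	length_bp	subgenome
1A	594102056	A
2A	780798557	A
3A	750843639	A
4A	744588157	A
5A	709773743	A
6A	618079260	A
7A	736706236	A
1B	689851870	B
2B	801256715	B
3B	830829764	B
4B	673617499	B
5B	713149757	B
6B	720988478	B
7B	750620385	B
1D	495453186	D
2D	651852609	D
3D	615552423	D
4D	509857067	D
5D	566080677	D
6D	473592718	D
7D	638686055	D
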