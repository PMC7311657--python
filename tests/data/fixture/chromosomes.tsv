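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
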