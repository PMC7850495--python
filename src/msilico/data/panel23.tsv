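# panel: panel23
# synthetic fixture panel on a toy genome (not hg19 coordinates)
# columns: chrom	start	end	marker_id	repeat_unit	ref_length
chr1	200	225	BAT25	T	25
chr1	600	626	BAT26	A	26
chr1	1000	1021	NR-21	A	21
chr1	1400	1422	NR-22	A	22
chr1	1800	1824	NR-24	A	24
chr1	2200	2227	NR-27	A	27
chr2	200	227	MONO-27	A	27
chr2	600	625	CAT25	T	25
chr2	1000	1016	MSI-09	T	16
chr2	1400	1421	MSI-10	A	21
chr2	1800	1815	MSI-11	T	15
chr2	2200	2220	MSI-12	A	20
chr3	200	225	MSI-13	T	25
chr3	600	619	MSI-14	A	19
chr3	1000	1024	MSI-15	T	24
chr3	1400	1418	MSI-16	A	18
chr3	1800	1823	MSI-17	T	23
chr3	2200	2217	MSI-18	A	17
chr4	200	222	MSI-19	T	22
chr4	600	616	MSI-20	A	16
chr4	1000	1021	MSI-21	T	21
chr4	1400	1415	MSI-22	A	15
chr4	1800	1820	MSI-23	T	20
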