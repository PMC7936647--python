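##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##INFO=<ID=QSS,Number=1,Type=Float,Description="Somatic quality score">
##INFO=<ID=DPT,Number=1,Type=Integer,Description="Read depth, treated sample">
##INFO=<ID=DPC,Number=1,Type=Integer,Description="Read depth, control sample">
##INFO=<ID=VS,Number=1,Type=Integer,Description="Reads supporting the variant">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
chr1	100	.	A	C	50	PASS	QSS=50;DPT=30;DPC=30;VS=10
chr1	150	.	G	T	39.5	PASS	QSS=39.5;DPT=30;DPC=30;VS=10
chr1	200	.	C	T	10	PASS	QSS=10;DPT=5;DPC=30;VS=2
chr1	250	.	T	A	41	PASS	QSS=41;DPT=19;DPC=30;VS=10
chr1	300	.	C	G	60	PASS	QSS=60;DPT=30;DPC=15;VS=10
chr1	350	.	A	G	60	PASS	QSS=60;DPT=30;DPC=30;VS=3
chr1	400	.	G	A	60	PASS	QSS=60;DPT=30;DPC=30;VS=4
chr1	500	.	C	T	60	PASS	QSS=60;DPT=30;DPC=30;VS=10
chr1	550	.	G	C	60	PASS	QSS=60;DPT=30;DPC=30;VS=10
chr1	600	.	A	C	40	PASS	QSS=40;DPT=30;DPC=30;VS=10
chr1	650	.	T	G	60	PASS	QSS=60;DPT=20;DPC=20;VS=5
chr1	700	.	C	A	60	PASS	QSS=60;DPT=30;DPC=30;VS=10
chr1	750	.	G	T	35	PASS	QSS=35;DPT=30;DPC=30;VS=10
chr1	800	.	T	C	50	PASS	QSS=50;DPT=10;DPC=30;VS=8
chr1	850	.	A	G	50	PASS	QSS=50;DPT=30;DPC=30;VS=0
chr1	900	.	C	G	60	PASS	QSS=60;DPT=30;DPC=30;VS=10
chr1	950	.	T	A	60	PASS	QSS=60;DPT=30;DPC=30;VS=10
chr1	1500	.	C	A	60	PASS	QSS=60;DPT=30;DPC=30;VS=10
chr1	2000	.	T	C	60	PASS	QSS=60;DPT=30;DPC=30;VS=10
chr1	2001	.	A	T	60	PASS	QSS=60;DPT=30;DPC=30;VS=10
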