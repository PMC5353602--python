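# Nearest-neighbor doublet parameters for DNA/DNA duplexes, 1 M NaCl reference state.
# step: top strand 5'->3' / bottom strand 3'->5' (as written, left to right).
# dH: kcal/mol; dS: cal/(K*mol). Lookup is symmetric under reversed strand reading.
step	dH	dS	source
init	0.2	-5.7	init_santalucia_hicks_2004
init_A/T	2.2	6.9	init_santalucia_hicks_2004
init_G/C	0	0	init_santalucia_hicks_2004
init_oneG/C	0	0	init_santalucia_hicks_2004
init_allA/T	0	0	init_santalucia_hicks_2004
init_5T/A	0	0	init_santalucia_hicks_2004
sym	0	-1.4	sym_santalucia_hicks_2004
AA/TT	-7.6	-21.3	wc_santalucia_hicks_2004
AT/TA	-7.2	-20.4	wc_santalucia_hicks_2004
TA/AT	-7.2	-21.3	wc_santalucia_hicks_2004
CA/GT	-8.5	-22.7	wc_santalucia_hicks_2004
GT/CA	-8.4	-22.4	wc_santalucia_hicks_2004
CT/GA	-7.8	-21.0	wc_santalucia_hicks_2004
GA/CT	-8.2	-22.2	wc_santalucia_hicks_2004
CG/GC	-10.6	-27.2	wc_santalucia_hicks_2004
GC/CG	-9.8	-24.4	wc_santalucia_hicks_2004
GG/CC	-8.0	-19.9	wc_santalucia_hicks_2004
AG/TT	1.0	0.9	mm_GT_allawi_santalucia_1997
AT/TG	-2.5	-8.3	mm_GT_allawi_santalucia_1997
CG/GT	-4.1	-11.7	mm_GT_allawi_santalucia_1997
CT/GG	-2.8	-8.0	mm_GT_allawi_santalucia_1997
GG/CT	3.3	10.4	mm_GT_allawi_santalucia_1997
GG/TT	5.8	16.3	mm_GT_allawi_santalucia_1997
GT/CG	-4.4	-12.3	mm_GT_allawi_santalucia_1997
GT/TG	4.1	9.5	mm_GT_allawi_santalucia_1997
TG/AT	-0.1	-1.7	mm_GT_allawi_santalucia_1997
TG/GT	-1.4	-6.2	mm_GT_allawi_santalucia_1997
TT/AG	-1.3	-5.3	mm_GT_allawi_santalucia_1997
AA/TG	-0.6	-2.3	mm_GA_allawi_santalucia_1998
AG/TA	-0.7	-2.3	mm_GA_allawi_santalucia_1998
CA/GG	-0.7	-2.3	mm_GA_allawi_santalucia_1998
CG/GA	-4.0	-13.2	mm_GA_allawi_santalucia_1998
GA/CG	-0.6	-1.0	mm_GA_allawi_santalucia_1998
GG/CA	0.5	3.2	mm_GA_allawi_santalucia_1998
TA/AG	0.7	0.7	mm_GA_allawi_santalucia_1998
TG/AA	3.0	7.4	mm_GA_allawi_santalucia_1998
AC/TT	0.7	0.2	mm_CT_allawi_santalucia_1998
AT/TC	-1.2	-6.2	mm_CT_allawi_santalucia_1998
CC/GT	-0.8	-4.5	mm_CT_allawi_santalucia_1998
CT/GC	-1.5	-6.1	mm_CT_allawi_santalucia_1998
GC/CT	2.3	5.4	mm_CT_allawi_santalucia_1998
GT/CC	5.2	13.5	mm_CT_allawi_santalucia_1998
TC/AT	1.2	0.7	mm_CT_allawi_santalucia_1998
TT/AC	1.0	0.7	mm_CT_allawi_santalucia_1998
AA/TC	2.3	4.6	mm_AC_allawi_santalucia_1998
AC/TA	5.3	14.6	mm_AC_allawi_santalucia_1998
CA/GC	1.9	3.7	mm_AC_allawi_santalucia_1998
CC/GA	0.6	-0.6	mm_AC_allawi_santalucia_1998
GA/CC	5.2	14.2	mm_AC_allawi_santalucia_1998
GC/CA	-0.7	-3.8	mm_AC_allawi_santalucia_1998
TA/AC	3.4	8.0	mm_AC_allawi_santalucia_1998
TC/AA	7.6	20.2	mm_AC_allawi_santalucia_1998
AA/TA	1.2	1.7	mm_like_peyret_1999
CA/GA	-0.9	-4.2	mm_like_peyret_1999
GA/CA	-2.9	-9.8	mm_like_peyret_1999
TA/AA	4.7	12.9	mm_like_peyret_1999
AC/TC	0.0	-4.4	mm_like_peyret_1999
CC/GC	-1.5	-7.2	mm_like_peyret_1999
GC/CC	3.6	8.9	mm_like_peyret_1999
TC/AC	6.1	16.4	mm_like_peyret_1999
AG/TG	-3.1	-9.5	mm_like_peyret_1999
CG/GG	-4.9	-15.3	mm_like_peyret_1999
GG/CG	-6.0	-15.8	mm_like_peyret_1999
TG/AG	1.6	3.6	mm_like_peyret_1999
AT/TT	-2.7	-10.8	mm_like_peyret_1999
CT/GT	-5.0	-15.8	mm_like_peyret_1999
GT/CT	-2.2	-8.4	mm_like_peyret_1999
TT/AT	0.2	-1.5	mm_like_peyret_1999
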