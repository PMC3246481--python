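# 43 tumour-immunosuppression candidate genes with functional subgroup labels.
# Coordinates are approximate NCBI build-36 gene spans (1-based, inclusive),
# reconstructed from public annotation; they are accurate to the ~10 kb scale
# that matters for 100 kb flanking and merging of co-located genes
# (CCL17/CCL22, CD274/PDCD1LG2 and CD28/ICOS/CTLA4 each collapse into a
# single region, giving 39 regions from 43 genes).
gene	chrom	start	end	subgroups
TNFRSF18	1	1138888	1142071	Treg
TGFBR3	1	92145899	92371559	Treg,tDC
CD160	1	145719465	145739297	Costim
IL10	1	205007871	205012761	Treg,tDC,Secreted
TGFB2	1	216586891	216682244	Treg,tDC,Secreted
CD28	2	204571198	204603635	Treg,Costim
CTLA4	2	204732511	204738683	Treg,Costim
ICOS	2	204801470	204826300	Treg,Costim
PDCD1	2	242792033	242801058	Costim
TGFBR2	3	30648066	30735634	Treg,tDC
IL17RB	3	53880755	53898818	Treg
CBLB	3	105655461	105869087	Anergy
BTLA	3	112181724	112215331	Costim
CD80	3	119244555	119280693	Costim
CD86	3	121774212	121839949	Costim
IL12A	3	159706529	159713800	Secreted
IL12B	5	158741791	158757481	Secreted
BTNL2	6	32470490	32482878	Costim
TREML2	6	41158421	41172616	Costim
IL17A	6	52051185	52055436	Treg,Secreted
IDO1	8	39871790	39886217	Treg,tDC,Secreted
CD274	9	5450503	5470567	Costim
PDCD1LG2	9	5510570	5571254	Costim
TGFBR1	9	101867380	101916474	Treg,tDC
IL10RA	11	117857063	117871821	Treg,tDC
VDR	12	48235320	48298814	Treg,tDC
DGKA	12	56324737	56347568	Anergy
LGALS3	14	55593270	55612900	Secreted
CCL22	16	57392684	57400102	Treg,Secreted
CCL17	16	57438679	57449974	Treg,Secreted
IL12RB1	19	18170371	18197697	Treg
TGFB1	19	41836813	41859831	Treg,tDC,Secreted
LILRB2	19	54777325	54784601	tDC
LILRB4	19	55173569	55179846	tDC
ITCH	20	32951041	33099198	Anergy
CD40	20	44180123	44192034	Costim
ICOSLG	21	45642874	45660083	Costim
IL10RB	21	33549011	33579764	Treg,tDC
IL17RA	22	17084954	17115693	Treg
LGALS1	22	38071614	38075813	Secreted
FOXP3	X	49106897	49121288	Treg
RNF128	X	105936069	106042072	Anergy
CD40LG	X	135730334	135742549	Costim
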