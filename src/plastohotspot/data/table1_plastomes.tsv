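species	total_bp	lsc_bp	ssc_bp	ir_bp	at_percent	accession	voucher
Dendrobium aphyllum	151524	84588	14320	26308	62.40	LC192953	NZT2015001
Dendrobium brymerianum	151830	84855	14377	26299	62.40	LC192954	NZT2015002
Dendrobium chrysanthum	151790	84757	14441	26296	62.44	LC193514	NZT2015003
Dendrobium chrysotoxum	151731	84785	14356	26295	62.37	LC193517	NZT2015004
Dendrobium crepidatum	151718	84811	14383	26262	62.43	LC193509	NZT2015005
Dendrobium denneanum	151565	84657	14344	26282	62.37	LC192955	NZT2015006
Dendrobium devonianum	151945	84966	14435	26272	62.45	LC192956	NZT2015007
Dendrobium ellipsophyllum	152026	84930	14488	26304	62.50	LC193519	NZT2015008
Dendrobium exile	151294	84363	14315	26308	62.32	LC193522	NZT2015009
Dendrobium falconeri	151890	84862	14448	26290	62.51	LC192957	NZT2015010
Dendrobium fanjingshanense	152108	84990	14514	26302	62.49	LC193523	NZT2015011
Dendrobium fimbriatum	151673	84763	14328	26291	62.40	LC193521	NZT2015012
Dendrobium gratiosissimum	151829	84890	14359	26290	62.43	LC192958	NZT2015013
Dendrobium henryi	151850	84878	14366	26303	62.44	LC193513	NZT2015014
Dendrobium hercoglossum	151939	84924	14397	26309	62.44	LC192959	NZT2015015
Dendrobium jenkinsii	151717	84734	14413	26285	62.40	LC193515	NZT2015016
Dendrobium lohohense	151812	84876	14352	26292	62.44	LC193516	NZT2015017
Dendrobium parciflorum	150073	83708	13821	26272	62.33	LC193512	NZT2015018
Dendrobium parishii	151689	84703	14396	26295	62.42	LC193518	NZT2015019
Dendrobium primulinum	150767	84442	13975	26175	62.27	LC192810	NZT2015020
Dendrobium salaccense	151104	84273	14315	26258	62.69	LC193510	NZT2015021
Dendrobium spatella	151829	84794	14419	26308	62.42	LC193511	NZT2015022
Dendrobium wardianum	151788	84835	14359	26297	62.43	LC192961	NZT2015023
Dendrobium wilsonii	152080	84988	14480	26306	62.49	LC193508	NZT2015024
Dendrobium xichouense	152052	84980	14486	26293	62.49	LC193520	NZT2015025
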