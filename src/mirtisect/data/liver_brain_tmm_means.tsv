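mirna_id	liver	brainstem	cerebellum	cerebrum	hippocampus
rno-miR-101b-3p	9673.302	259.23	9333.53	2239.78	3325.597
rno-miR-122-3p	4009.98	0.168	0.045	0.134	0.092
rno-miR-122-5p	69427.419	0.428	0.87	0.69	1.574
rno-miR-142-3p	363.858	26.372	10.863	12.454	61.031
rno-miR-142-5p	3637.916	118.302	71.591	102.668	682.414
rno-miR-144-3p	579.159	22.386	16.137	11.014	16.39
rno-miR-144-5p	679.886	37.424	22.018	18.614	20.869
rno-miR-192-5p	468832.182	273.309	4705.168	1628.248	49459.205
rno-miR-193-3p	1737.21	15.646	5.535	10.126	71.69
rno-miR-194-5p	29022.858	222.803	1005.578	154.443	4888.132
rno-miR-203b-3p	346.805	0.549	0.34	1.926	5.414
rno-miR-21-5p	159245.015	3854.307	1345.632	1652.192	15147.209
rno-miR-22-3p	1236523.448	96603.646	55374.293	166371.249	235026.152
rno-miR-22-5p	444.407	63.992	28.289	87.822	84.76
rno-miR-31a-3p	135.821	4.969	0.734	4.788	12.909
rno-miR-31a-5p	2931.165	168.328	32.897	158.017	583.204
rno-miR-339-5p	314.445	49.849	25.719	27.668	43.617
rno-miR-3559-5p	550.276	11.454	11.879	13.587	34.687
rno-miR-365-3p	470.536	26.121	10.247	22.187	60.292
rno-miR-378a-3p	16034.731	383.201	604.102	379.106	1496.621
rno-miR-378a-5p	412.681	12.512	54.307	8.676	41.054
rno-miR-451-5p	1297.679	81.875	47.434	43.356	53.144
rno-miR-6329	158.695	15.135	17.172	11.838	23.729
rno-miR-802-3p	2405.619	0.794	0.317	2.248	50.689
rno-miR-802-5p	294.88	0.093	0	0.027	6.983
rno-miR-92a-1-5p	270.871	10.879	2.949	8.154	37.219
rno-miR-92a-3p	16055.859	197.271	58.193	158.198	198.4
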