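chrom	pos_bp	marker	rsid	ihs	pihs
13	35005345	BTB-01342926	rs42469902	-5.699	7.919
13	36785616	BTA-32337-no-rs	rs41628271	-5.521	7.472
13	37861193	ARS-BFGL-NGS-103989	rs109603252	-5.578	7.613
13	39528648	ARS-BFGL-NGS-65199	rs110693756	6.936	11.395
13	40080019	Hapmap50934-BTA-32439	rs41628321	-6.16	9.139
13	40943586	ARS-BFGL-NGS-22137	rs109374197	-5.685	7.885
13	41164136	ARS-BFGL-NGS-102025	rs110274438	-5.421	7.227
13	41383107	ARS-BFGL-NGS-13176	rs109765738	-5.17	6.632
13	41433750	Hapmap47567-BTA-32536	rs41629073	-5.143	6.568
13	41467021	Hapmap58859-rs29023610	rs29023610	-5.142	6.567
13	41504180	BTA-32538-no-rs	rs41584360	-6.07	8.893
13	41826984	ARS-BFGL-NGS-14104	rs110783267	-7.64	13.662
13	41935549	BTB-00523176	rs41689217	6.019	8.755
13	42741708	ARS-BFGL-NGS-100409	rs110687098	-6.898	11.278
13	44040542	BTB-01254653	rs42074017	-6.672	10.599
13	44978611	ARS-BFGL-NGS-23830	rs42496808	-5.389	7.149
13	45034339	ARS-BFGL-NGS-18246	rs110155669	-6.545	10.224
13	45697341	BTA-73938-no-rs	rs41590789	-5.121	6.518
13	46089659	ARS-BFGL-NGS-35887	rs108961732	-5.989	8.675
13	47725601	ARS-BFGL-NGS-84799	rs110840150	-5.739	8.020
13	48120211	ARS-BFGL-NGS-35327	rs41696855	-5.23	6.771
13	48456319	BTA-115847-no-rs	rs43706693	5.674	7.856
13	52247494	ARS-BFGL-NGS-35859	rs109671123	5.047	6.349
13	52480216	ARS-BFGL-NGS-21294	rs109138166	-5.268	6.860
13	52623427	Hapmap47571-BTA-32877	rs41630007	-5.91	8.466
13	53871753	ARS-BFGL-NGS-82210	rs109449298	4.962	6.157
13	54192189	ARS-BFGL-NGS-33209	rs109508313	-4.962	6.157
13	55149168	ARS-BFGL-NGS-104967	rs41697716	5.31	6.961
13	55687392	Hapmap38200-BTA-120950	rs41624058	-5.818	8.225
13	55819574	BTA-32981-no-rs	rs41630656	5.531	7.496
13	57449072	BTB-00531090	rs41694639	-6.276	9.460
13	57988686	Hapmap58840-rs29018856	rs29018856	-5.287	6.904
14	17877847	UA-IFASA-6459	rs42422981	-5.767	8.092
14	24790463	Hapmap32434-BTC-011497	rs41726059	-4.904	6.026
14	26212648	Hapmap33173-BTC-073249	rs43054543	-5.105	6.481
21	19448733	ARS-BFGL-BAC-33343	rs110246265	-5.245	6.806
29	28560818	ARS-BFGL-NGS-18412	rs110263608	5.588	7.640
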