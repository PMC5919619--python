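q1	q3	polarity	scan	printed_attribution	canonical	fold_change	p_value
650.3	282.1	+	Ceramide	CerAP(t18:0/22:0)2OH	CerAP(t18:0/22:0)2OH	5.24	3.67e-21
650.4	264.1	+	Ceramide	CerNS(d18:1/24:0)	CerNS(d18:1/24:0)	7.31	5.40e-19
622.1	264.1	+	Ceramide	CerNS(d18:1/22:0)	CerNS(d18:1/22:0)	5.76	4.61e-18
694.15	264.1	+	Ceramide	CerAS(d18:1/26:0)2OH	CerAS(d18:1/26:0)2OH	4.85	1.54e-17
554.2	264.1	+	Ceramide	CerAS(d18:1/16:0)2OH	CerAS(d18:1/16:0)2OH	5.23	1.22e-15
554.2	282.1	+	Ceramide	CerAP(t18:0/16:0)2OH	CerAP(t18:0/16:0)2OH	4.48	6.96e-15
536.1	264.1	+	Ceramide	CerNS(d18:1/16:1)	CerNS(d18:1/16:1)	4.66	8.34e-15
538.3	264.1	+	Ceramide	CerNS(d18:1/16:0)	CerNS(d18:1/16:0)	4.89	1.02e-14
666.35	264.1	+	Ceramide	CerAS(d18:1/24:0)2OH	CerAS(d18:1/24:0)2OH	18.73	1.25e-14
648.4	264.1	+	Ceramide	CerNS(d18:1/24:1)	CerNS(d18:1/24:1)	3.64	1.64e-12
271.3	271.3	-	FFA	16-hydroxy(16:0)	FFA(16:0)OH	2.31	7.67e-12
761.9	184.1	+	PC	SM(d18:0/20:0) SM(d16:0/22:0) posible isotope PC(34:1)	SM(d18:0/20:0)|SM(d16:0/22:0)	2.62	4.01e-09
538.2	282.1	+	Ceramide	CerNP(t18:0/16:0)	CerNP(t18:0/16:0)	2.03	2.21e-08
484	85.1	+	Acylcarnitine	AC(18:0)	AC(18:0)	2.73	5.31e-08
703.8	184.1	+	PC	SM(16:0)	SM(d18:1/16:0)	2.41	7.37e-08
456.3	85.1	+	Acylcarnitine	AC(16:0)	AC(16:0)	4.02	1.32e-07
438.05	266.1	+	Ceramide	CerDS(18:0/10:0)	CerDS(d18:0/10:0)	2.26	1.37e-07
746.8	184.1	+	PC	ePC(34:1) / pPC(34:0)	ePC(34:1)|pPC(34:0)	2.01	7.87e-07
734.8	184.1	+	PC	PC(32:0)	PC(32:0)	2.23	9.37e-07
662.3	341.3	+	NL AA	Not attributted		3.44	1.82e-06
760.8	184.1	+	PC	PC(34:1)	PC(34:1)	2.12	2.85e-06
758.8	184.1	+	PC	PC(34:2)	PC(34:2)	2.11	5.11e-06
634.3	313.3	+	NL AA	Not attributed		2.81	6.20e-06
487.5	487.5	-	FFA	Not attributed		0.42	7.40e-06
689.8	184.1	+	PC	PG(30:3) SM(d16:1/17:0) SM(d18:1/15:0)	SM(d16:1/17:0)|SM(d18:1/15:0)	0.50	8.68e-06
788.9	184.1	+	PC	PC(36:1)	PC(36:1)	2.02	1.32e-05
787.9	184.1	+	PC	SM(d18:1/22:0) SM(d16:1/24:0)	SM(d18:1/22:0)|SM(d16:1/24:0)	2.06	1.95e-05
395.4	395.4	-	FFA	C26:0	FFA(26:0)	0.23	3.85e-05
372.2	85.1	+	Acylcarnitine	AC(10:0)	AC(10:0)	0.49	5.94e-05
400.3	85.1	+	Acylcarnitine	AC(12:0)	AC(12:0)	0.48	6.53e-05
414.3	85.1	+	Acylcarnitine	AC(12:1)OH	AC(12:1)OH	0.48	2.63e-04
426.3	85.1	+	Acylcarnitine	AC(14:1)	AC(14:1)	0.48	4.44e-04
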