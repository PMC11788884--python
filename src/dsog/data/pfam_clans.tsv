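accession	clan	clan_name
PF00047	CL0011	Ig
PF07679	CL0011	Ig
PF07686	CL0011	Ig
PF08205	CL0011	Ig
PF13895	CL0011	Ig
PF13927	CL0011	Ig
PF00008	CL0001	EGF
PF07645	CL0001	EGF
PF12662	CL0001	EGF
PF14670	CL0001	EGF
PF00050	CL0005	Kazal
PF07648	CL0005	Kazal
PF00089	CL0124	Peptidase_PA
PF13365	CL0124	Peptidase_PA
PF09342	CL0124	Peptidase_PA
PF13620	CL0159	E-set
PF13715	CL0159	E-set
PF00413	CL0126	Peptidase_MA
PF01400	CL0126	Peptidase_MA
PF01437	CL0659	PSI
PF17205	CL0659	PSI
PF12799	CL0022	LRR
PF13306	CL0022	LRR
PF13855	CL0022	LRR
PF00622	CL0014	B30.2-SPRY
PF13765	CL0014	B30.2-SPRY
PF13465	CL0361	zf-C2H2
PF13894	CL0361	zf-C2H2
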