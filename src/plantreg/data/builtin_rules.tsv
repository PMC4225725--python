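# Starter prediction-logic table.
# Columns: family, regulator category (TF/TR/CR/Other), must-have expression,
# prohibited expression ("-" = none).
#
# Curation status:
#   ARF, MADS type1, MADS-MICK — complete as published (IPR010525 Aux/IAA-ARF
#   dimerisation, IPR011525 Aux/IAA, IPR003340 B3 DNA-binding, IPR002100 MADS
#   box, IPR002487 K-box).
#   B3 / AP2-EREBP / RAV — superfamily split via prohibitions; the AP2 atom
#   IPR001471 is standard InterPro but REQUIRES CURATION against the full
#   published family list.
#   BTB-POZ-MATH / ABTB — BTB/POZ core via PROSITE PS50097 or SMART SM00225;
#   companion atoms IPR002083 (MATH) and IPR002110 (ankyrin) REQUIRE CURATION.
family	category	must_have	prohibited
ARF	TF	(IPR010525|IPR011525)&IPR003340	-
MADS type1	TF	IPR002100	IPR002487
MADS-MICK	TF	IPR002100&IPR002487	-
B3	TF	IPR003340	IPR001471|IPR010525|IPR011525
AP2-EREBP	TF	IPR001471	IPR003340
RAV	TF	IPR003340&IPR001471	IPR010525|IPR011525
BTB-POZ-MATH	TR	(PS50097|SM00225)&IPR002083	IPR002110
ABTB	TR	(PS50097|SM00225)&IPR002110	IPR002083
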