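# IASLC nodal-station map, version 1.0 (8th-edition clinical N staging).
# Columns: station <TAB> description <TAB> ipsilateral <TAB> contralateral
# "ipsilateral"/"contralateral" give the regionality class when the node lies on the
# same/opposite side as the primary tumor.  Special cases:
#   station 1  - low cervical / supraclavicular / sternal notch: N3 from either side
#   station 7  - subcarinal, midline: N2 regardless of primary side
#   stations 5,6 - aortopulmonary window / para-aortic: left-sided structures; the
#                  side columns are interpreted against the PRIMARY side
# Tokens with class "extrathoracic" are outside the map: such nodes are distant
# disease (M), never regional (N).
station	description	ipsilateral	contralateral
1	low cervical / supraclavicular / sternal notch	N3	N3
2	upper paratracheal	N2	N3
3	prevascular / retrotracheal	N2	N3
4	lower paratracheal	N2	N3
5	subaortic (aortopulmonary window)	N2	N3
6	para-aortic (ascending aorta / phrenic)	N2	N3
7	subcarinal	N2	N2
8	paraesophageal (below carina)	N2	N3
9	pulmonary ligament	N2	N3
10	hilar	N1	N3
11	interlobar	N1	N3
12	lobar	N1	N3
13	segmental	N1	N3
14	subsegmental	N1	N3
axillary	axillary nodes (not in the IASLC map)	extrathoracic	extrathoracic
abdominal	abdominal nodes	extrathoracic	extrathoracic
inguinal	inguinal nodes	extrathoracic	extrathoracic
internal_mammary	internal mammary nodes	extrathoracic	extrathoracic
diaphragmatic	diaphragmatic nodes	extrathoracic	extrathoracic
retroperitoneal	retroperitoneal nodes	extrathoracic	extrathoracic
cervical	cervical nodes above the supraclavicular zone	extrathoracic	extrathoracic
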