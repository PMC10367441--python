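subject,high,low,combined
sub-001,0.0599287494360441,-0.028061024978063565,0.08798977441410766
sub-002,0.08121175560250199,-0.03250443644341228,0.11371619204591427
sub-003,0.05468178606176128,-0.011123309521821225,0.06580509558358251
sub-004,0.05186591132572861,0.024698619648949087,0.027167291676779524
sub-005,0.09474155464818325,-0.005174968831793612,0.09991652347997686
sub-006,0.05321798401815278,0.014226046905674713,0.038991937112478066
sub-007,0.05432331261754249,-0.010946244168933953,0.06526955678647645
sub-008,0.051523386863322126,0.026926578473554934,0.024596808389767192
sub-009,0.05709548625788125,-0.0022954840171926843,0.05939097027507394
sub-010,0.0747949585140191,0.0062120905965443495,0.06858286791747475
sub-011,0.06863521389946972,-0.003333796921819109,0.07196901082128883
sub-012,0.05620644703643169,-0.010020541662678758,0.06622698869911045
sub-013,0.03804510029747174,-0.019225968442432205,0.057271068739903945
sub-014,0.03832622520397886,0.021044397611100028,0.017281827592878832
sub-015,0.05245650195285639,0.043671169087044714,0.008785332865811672
sub-016,0.05374462124492807,-0.017814993553481547,0.07155961479840961
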