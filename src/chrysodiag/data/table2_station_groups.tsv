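location	group
Baker street	Bakerloo Line
Edgware road	Bakerloo Line
Marylebone	Bakerloo Line
Paddington	Bakerloo Line
Chancery lane	Central Line
Holborn	Central Line
Oxford circus	Central Line
Tottenham court road	Central Line
Bond street	Jubilee Line
Green park	Jubilee Line
Waterloo	Jubilee Line
Westminster	Jubilee Line
Hospital corridor	St Mary's Hospital
A&E	St Mary's Hospital
Alexander Fleming's lab	St Mary's Hospital
DIDE laboratory	St Mary's Hospital
Norfolk square gardens	Outdoors
Canal	Outdoors
Praed street	Outdoors
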