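location,chrysogenum,rubens,other
Baker street,5,0,17
Edgware road,4,3,24
Marylebone,3,5,32
Paddington,5,3,31
Chancery lane,5,6,19
Holborn,7,9,11
Oxford circus,5,6,24
Tottenham court road,6,9,18
Bond street,9,6,17
Green park,0,2,15
Waterloo,0,2,6
Westminster,1,4,11
Hospital corridor,3,0,9
A&E,0,2,14
Alexander Fleming's lab,3,4,13
DIDE laboratory,0,1,3
Norfolk square gardens,1,2,13
Canal,1,1,14
Praed street,0,0,16
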