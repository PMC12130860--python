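(Domestic_cat:94,(Mouse:87,('Aye-aye':74,(Owl_monkey:43,((Olive_baboon:12,Rhesus_macaque:12):17,(Human:7,Chimpanzee:7):22):14):31):13):7);
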