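family	substrate
GH5	cellulose
GH6	cellulose
GH8	cellulose
GH9	cellulose
GH12	cellulose
GH44	cellulose
GH45	cellulose
GH48	cellulose
GH1	oligosaccharides
GH2	oligosaccharides
GH3	oligosaccharides
GH31	oligosaccharides
GH13	starch
GH15	starch
GH57	starch
GH77	starch
GH27	starch
GH32	fructans
GH68	fructans
GH30	xylans
GH10	xylans
GH11	xylans
GH16	plant polysaccharides
GH28	plant polysaccharides
GH18	chitin
GH19	chitin
GH20	chitin
GH23	mixed
GH74	mixed
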