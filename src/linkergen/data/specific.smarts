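# Motifs treated as synthetically challenging or chemically unstable when
# they appear in an assembled PROTAC. One SMARTS per line; '#' comments.
# User-replaceable via the run configuration.
[CX4H0,CX4H1]([OX2,NX3,SX2])([OX2,NX3,SX2])  # acetal/aminal: two heteroatoms on one sp3 carbon
[OX2][OX2]                                   # O-O single bond (peroxide)
[NX3][NX3][NX3]                              # N-N-N chain
[CX3]=[CX3][OX2][CX4]                        # enol ether
[CX4]([OX2H])[NX3]                           # hemiaminal
[CX4]([F,Cl,Br,I])[OX2]                      # alpha-halo ether
[CX3](=[OX1])[OX2][CX3](=[OX1])              # anhydride
[NX3][CX4][NX3]                              # aminal (N-C-N)
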