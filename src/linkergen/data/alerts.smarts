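# Structural alert patterns flagged as reactive, unstable or otherwise
# undesirable in assembled PROTACs. One SMARTS per line; '#' comments.
# The list is deliberately conservative and fully user-replaceable via the
# run configuration.
[CX3H1](=O)[#6]            # aldehyde
[CX3](=O)[F,Cl,Br,I]       # acyl halide
[SX2][SX2]                 # disulfide
[OX2][OX2]                 # peroxide
[NX3][NX3][NX3]            # triamine chain / azide-like N-N-N
[N;X2]=[N;X2]              # azo
[NX2]=[NX2+]=[NX1-]        # azide
[NX3][NX2]=[OX1]           # nitrosamine
[NX2]=[OX1]                # nitroso
[N+](=O)[O-]               # nitro
[CX3]=[NX2][OX2H]          # oxime
C1OC1                      # epoxide
C1NC1                      # aziridine
[SX2H]                     # thiol
[CX3](=O)O[CX3](=O)        # anhydride
[CX3](=S)                  # thiocarbonyl
[SX4](=O)(=O)[F,Cl,Br,I]   # sulfonyl halide
[PX3,PX4][F,Cl,Br,I]       # phosphorus halide
[CH2X4][Cl,Br,I]           # primary alkyl halide (alkylating)
[CX3]=[CX3][CX3]=[OX1]     # Michael acceptor (enone)
[CX3]=[CX3][SX4](=O)(=O)   # vinyl sulfone
[CX3]=[CX3][C]#[N]         # acrylonitrile-like acceptor
[NX1]#[CX2][!#7]           # isonitrile-adjacent / reactive nitrile carbon
[NX2]=[CX2]=[OX1]          # isocyanate
[NX2]=[CX2]=[SX1]          # isothiocyanate
O=[CX3](O[#6])O[#6]        # carbonate-like diester carbon
[OX1]=[CX3][CX3]=[OX1]     # 1,2-dicarbonyl
O=C1C=CC(=O)C=C1           # para-quinone
O=C1C(=O)C=CC=C1           # ortho-quinone
[CX4]([F,Cl,Br,I])([F,Cl,Br,I])[F,Cl,Br,I]  # perhaloalkyl carbon
[Si]                       # silicon
[B]                        # boron
[Se,Te]                    # selenium / tellurium
[#6]=[#6]=[#6]             # allene
C#C[CX3]=[OX1]             # ynone
[OX2H][NX3]                # hydroxylamine
[NX3H2][NX3H1,NX3H2]       # hydrazine
[CX3]=[NX2][NX3]           # hydrazone
[cX3][OX2][cX3]1ccccc1O    # catechol ether-like redox motif
[SX3](=O)[F,Cl,Br,I]       # sulfinyl halide
[CX4]([OX2H])[OX2H]        # geminal diol
[CX3](=O)[CX3](=O)[OX2H]   # alpha-keto acid
[N;R0]=[N;R0]C#N           # azocarbonitrile
[CH]=[CH][OX2H]            # enol
[#7][F,Cl,Br,I]            # N-halogen
[#8][F,Cl,Br,I]            # O-halogen
[CX2]#[CX2H]               # terminal alkyne (clickable, flagged)
[N+]#[C-]                  # isocyanide
[CX3](=[OX1])[OX2][NX3]    # activated ester of hydroxylamine
[#16X2][CX3]=[OX1]         # thioester
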