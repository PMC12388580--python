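# Persistent-microbiome membership reported for the GFP larval study
# (Macrobrachium rosenbergii larvae, Dph 1-21, NMDC10019917-derived dataset).
# One row per reported persistent member. The single Deinococcota member was
# reported only at phylum level; its asv_id is left empty.
lineage	asv_id
Deinococcota	
Bacillota	ASV115
Bacillota	ASV117
Planctomycetota	ASV72
Planctomycetota	ASV85
Actinomycetota	ASV26
Actinomycetota	ASV48
Actinomycetota	ASV49
Actinomycetota	ASV62
Actinomycetota	ASV120
Actinomycetota	ASV186
Bacteroidota	ASV4
Bacteroidota	ASV16
Bacteroidota	ASV17
Bacteroidota	ASV20
Bacteroidota	ASV31
Bacteroidota	ASV38
Bacteroidota	ASV60
Bacteroidota	ASV63
Bacteroidota	ASV64
Bacteroidota	ASV68
Bacteroidota	ASV76
Bacteroidota	ASV125
Bacteroidota	ASV134
Alphaproteobacteria	ASV2
Alphaproteobacteria	ASV18
Alphaproteobacteria	ASV19
Alphaproteobacteria	ASV21
Alphaproteobacteria	ASV24
Alphaproteobacteria	ASV25
Alphaproteobacteria	ASV29
Alphaproteobacteria	ASV32
Alphaproteobacteria	ASV33
Alphaproteobacteria	ASV35
Alphaproteobacteria	ASV40
Alphaproteobacteria	ASV41
Alphaproteobacteria	ASV43
Alphaproteobacteria	ASV44
Alphaproteobacteria	ASV50
Alphaproteobacteria	ASV53
Alphaproteobacteria	ASV57
Alphaproteobacteria	ASV58
Alphaproteobacteria	ASV59
Alphaproteobacteria	ASV75
Alphaproteobacteria	ASV96
Alphaproteobacteria	ASV97
Alphaproteobacteria	ASV102
Alphaproteobacteria	ASV119
Alphaproteobacteria	ASV141
Alphaproteobacteria	ASV142
Gammaproteobacteria	ASV1
Gammaproteobacteria	ASV3
Gammaproteobacteria	ASV6
Gammaproteobacteria	ASV7
Gammaproteobacteria	ASV8
Gammaproteobacteria	ASV10
Gammaproteobacteria	ASV14
Gammaproteobacteria	ASV15
Gammaproteobacteria	ASV23
Gammaproteobacteria	ASV28
Gammaproteobacteria	ASV30
Gammaproteobacteria	ASV42
Gammaproteobacteria	ASV46
Gammaproteobacteria	ASV52
Gammaproteobacteria	ASV54
Gammaproteobacteria	ASV61
Gammaproteobacteria	ASV79
Gammaproteobacteria	ASV83
Gammaproteobacteria	ASV90
Gammaproteobacteria	ASV101
Gammaproteobacteria	ASV104
Gammaproteobacteria	ASV106
Gammaproteobacteria	ASV107
Gammaproteobacteria	ASV111
Gammaproteobacteria	ASV112
Gammaproteobacteria	ASV113
Gammaproteobacteria	ASV116
Gammaproteobacteria	ASV124
Gammaproteobacteria	ASV135
Gammaproteobacteria	ASV155
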