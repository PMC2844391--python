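property,group,residues
hydrophobicity,low,RKEDQN
hydrophobicity,medium,GASTPHY
hydrophobicity,high,CLVIMFW
polarity,low,LIFWCMVY
polarity,medium,PATGS
polarity,high,HQRKNED
polarizability,low,GASDT
polarizability,medium,CPNVEQIL
polarizability,high,KMHFRYW
vdw_volume,low,GASTPDC
vdw_volume,medium,NVEQIL
vdw_volume,high,MHKFRYW
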