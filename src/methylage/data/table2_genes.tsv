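# The 14 multifunction genes (>= 4 functional processes) among the 33 with
# an opposite methylation/expression trend, ordered by number of processes.
# direction: expression change with age (S+3 vs S+1); regulatory: gene has a
# differentially methylated CpG in a regulating area (promoter, first exon
# or first intron).  Synthetic transcription of a published summary table.
gene	n	direction	regulatory	processes
sirt1	11	up	1	Anatomical structure development,Anatomical structure formation,Anatomical structure morphogenesis,Reg. cel. process,Reg. developmental process,Reg. multicel. organismal process,Response to chemical,Response to endogenous stimulus,Rhythmic process,System development,Tissue development
smad1	11	up	1	Anatomical structure development,Anatomical structure formation,Anatomical structure morphogenesis,Animal organ development,Ossification,Reg. cel. process,Reg. developmental process,Reg. multicel. organismal process,Response to endogenous stimulus,System development,Tissue development
col5a1	10	down	1	Anatomical structure development,Anatomical structure formation,Anatomical structure morphogenesis,Animal organ development,Cell differentiation,Cel. component organization,Reg. cel. process,Reg. developmental process,System development,Tissue development
calcrl	8	down	1	Anatomical structure development,Anatomical structure formation,Anatomical structure morphogenesis,Animal organ development,Reg. cel. process,Reg. multicel. organismal process,Response to chemical,System development
nrp2	8	down	0	Anatomical structure development,Anatomical structure formation,Anatomical structure morphogenesis,Animal organ development,Cel. component organization,Reg. cel. process,Response to endogenous stimulus,System development
bmp1	8	down	1	Anatomical structure morphogenesis,Animal organ development,Cel. component organization,Ossification,Reg. developmental process,Reg. multicel. organismal process,System development,Tissue development
ramp1	6	up	1	Anatomical structure development,Anatomical structure formation,Anatomical structure morphogenesis,Reg. cel. process,Response to endogenous stimulus,System development
abi3bp	6	down	0	Animal organ development,Cel. component organization,Reg. cel. process,Reg. developmental process,Reg. multicel. organismal process,System development
mical2	5	down	0	Anatomical structure development,Anatomical structure morphogenesis,Animal organ development,Cel. component organization,System development
thrb	5	down	1	Anatomical structure development,Anatomical structure morphogenesis,Animal organ development,Response to endogenous stimulus,System development
spred2	5	down	1	Animal organ development,Reg. developmental process,Reg. multicel. organismal process,Response to endogenous stimulus,System development
arhgap24	4	down	0	Anatomical structure development,Anatomical structure formation,Anatomical structure morphogenesis,System development
psmd2	4	up	1	Anatomical structure morphogenesis,N compound met. process,Reg. developmental process,System development
atp1a2	4	down	1	Reg. localization,Reg. multicel. organismal process,Response to endogenous stimulus,Transport
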