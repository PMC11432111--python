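# Functional processes (GO-BP ancestors) of the 33 genes with an opposite
# methylation/expression trend, ordered by number of linked genes.
# up_genes lists the subset of the row's genes that are hypo-methylated and
# up-regulated with age; the remaining genes are hyper-methylated and
# down-regulated.  Synthetic transcription of a published summary table.
process	n	genes	up_genes
System development	17	abi3bp,arhgap24,bmp1,calcrl,col5a1,kcp,mical2,myo18b,nrp2,spred2,thrb,wfikkn2,parp3,psmd2,ramp1,sirt1,smad1	parp3,psmd2,ramp1,sirt1,smad1
Anatomical structure development	12	arhgap24,calcrl,col5a1,kidins220,mical2,myo18b,nrp2,thrb,phf6,ramp1,sirt1,smad1	phf6,ramp1,sirt1,smad1
Anatomical structure morphogenesis	12	arhgap24,bmp1,calcrl,col5a1,mical2,myo18b,nrp2,thrb,psmd2,ramp1,sirt1,smad1	psmd2,ramp1,sirt1,smad1
Reg. multicel. organismal process	11	abi3bp,atp1a2,bmp1,calcrl,sema6d,spred2,zbtb20,parp3,scn3b,sirt1,smad1	parp3,scn3b,sirt1,smad1
Cel. component organization	10	abi3bp,bmp1,col5a1,col6a3,colgalt1,kirrel1,mical2,nrp2,olfml2a,myoz2	myoz2
Response to endogenous stimulus	10	atp1a2,kcp,kidins220,nrp2,spred2,thrb,wfikkn2,ramp1,sirt1,smad1	ramp1,sirt1,smad1
Animal organ development	9	abi3bp,bmp1,calcrl,col5a1,mical2,nrp2,spred2,thrb,smad1	smad1
Reg. cel. process	9	abi3bp,calcrl,col5a1,colgalt1,ksr1,nrp2,ramp1,sirt1,smad1	ramp1,sirt1,smad1
Anatomical structure formation	8	arhgap24,calcrl,col5a1,nrp2,myoz2,ramp1,sirt1,smad1	myoz2,ramp1,sirt1,smad1
Reg. developmental process	8	abi3bp,bmp1,col5a1,sema6d,spred2,psmd2,sirt1,smad1	psmd2,sirt1,smad1
Reg. localization	4	atp1a2,fgf14,hecw2,scn3b	scn3b
Tissue development	4	bmp1,col5a1,sirt1,smad1	sirt1,smad1
Transport	4	atp1a2,fgf14,hecw2,scn3b	scn3b
Response to chemical	3	calcrl,zbtb20,sirt1	sirt1
N compound met. process	2	psmd2,srm	psmd2
Ossification	2	bmp1,smad1	smad1
Rhythmic process	2	tef,sirt1	tef,sirt1
Cell differentiation	1	col5a1	
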