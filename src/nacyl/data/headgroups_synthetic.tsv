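name	formula	diagnostic_fragments	n_sites	equivalence_group
glycine	C2H5NO2	76.039304@0.02@0.01;58.028739@0.02@0.01	1	
alanine	C3H7NO2	90.054954@0.02@0.01;72.044389@0.02@0.01	1	ala_iso
serine	C3H7NO3	106.049869@0.02@0.01;88.039304@0.02@0.01	1	
cysteine	C3H7NO2S	122.027026@0.02@0.01;104.016461@0.02@0.01	1	
aspartic acid	C4H7NO4	134.044784@0.02@0.01;116.034219@0.02@0.01	1	
asparagine	C4H8N2O3	133.060768@0.02@0.01;115.050203@0.02@0.01	1	
threonine	C4H9NO3	120.065519@0.02@0.01;102.054954@0.02@0.01	1	
glutamic acid	C5H9NO4	148.060434@0.02@0.01;130.049869@0.02@0.01	1	
glutamine	C5H10N2O3	147.076418@0.02@0.01;129.065853@0.02@0.01	1	
proline	C5H9NO2	116.070605@0.02@0.01;98.060040@0.02@0.01	1	
valine	C5H11NO2	118.086255@0.02@0.01;100.075690@0.02@0.01	1	
methionine	C5H11NO2S	150.058326@0.02@0.01;132.047761@0.02@0.01	1	
lysine	C6H14N2O2	147.112804@0.02@0.01;129.102239@0.02@0.01	2	
leucine	C6H13NO2	132.101905@0.02@0.01;114.091340@0.02@0.01	1	leu_iso
isoleucine	C6H13NO2	132.101905@0.02@0.01;114.091340@0.02@0.01	1	leu_iso
histidine	C6H9N3O2	156.076753@0.02@0.01;138.066188@0.02@0.01	1	
arginine	C6H14N4O2	175.118952@0.02@0.01;157.108387@0.02@0.01	1	
phenylalanine	C9H11NO2	166.086255@0.02@0.01;148.075690@0.02@0.01	1	
tyrosine	C9H11NO3	182.081169@0.02@0.01;164.070604@0.02@0.01	1	
tryptophan	C11H12N2O2	205.097154@0.02@0.01;187.086589@0.02@0.01	1	
sarcosine	C3H7NO2	90.054954@0.02@0.01;72.044389@0.02@0.01	1	ala_iso
beta-alanine	C3H7NO2	90.054954@0.02@0.01;72.044389@0.02@0.01	1	ala_iso
homoserine	C4H9NO3	120.065519@0.02@0.01;102.054954@0.02@0.01	1	
ornithine	C5H12N2O2	133.097154@0.02@0.01;115.086589@0.02@0.01	2	
citrulline	C6H13N3O3	176.102967@0.02@0.01;158.092402@0.02@0.01	1	
aminoadipic acid	C6H11NO4	162.076084@0.02@0.01;144.065519@0.02@0.01	1	
GABA	C4H9NO2	104.070605@0.02@0.01;86.060040@0.02@0.01	1	
2-aminobutyric acid	C4H9NO2	104.070605@0.02@0.01;86.060040@0.02@0.01	1	
5-aminovaleric acid	C5H11NO2	118.086255@0.02@0.01;100.075690@0.02@0.01	1	
homocysteine	C4H9NO2S	136.042676@0.02@0.01;118.032111@0.02@0.01	1	
selenomethionine	C5H11NO2Se	198.002776@0.02@0.01;179.992211@0.02@0.01	1	
3-methoxytyrosine	C10H13NO4	212.091734@0.02@0.01;194.081169@0.02@0.01	1	
ethanolamine	C2H7NO	62.060040@0.02@0.01;44.049475@0.02@0.01	1	
1,3-diaminopropane	C3H10N2	75.091674@0.02@0.01;58.065125@0.02@0.01	2	
putrescine	C4H12N2	89.107324@0.02@0.01;72.080775@0.02@0.01	2	
cadaverine	C5H14N2	103.122974@0.02@0.01;86.096425@0.02@0.01	2	
spermidine	C7H19N3	146.165174@0.02@0.01;129.138625@0.02@0.01	2	
spermine	C10H26N4	203.223023@0.02@0.01;186.196474@0.02@0.01	2	
agmatine	C5H14N4	131.129122@0.02@0.01;114.102573@0.02@0.01	1	
taurine	C2H7NO3S	126.021940@0.02@0.01;108.011375@0.02@0.01	1	
histamine	C5H9N3	112.086923@0.02@0.01;95.060374@0.02@0.01	1	
dopamine	C8H11NO2	154.086255@0.02@0.01;136.075690@0.02@0.01	1	
serotonin	C10H12N2O	177.102239@0.02@0.01;159.091674@0.02@0.01	1	
tyramine	C8H11NO	138.091340@0.02@0.01;120.080775@0.02@0.01	1	
tryptamine	C10H12N2	161.107324@0.02@0.01;144.080775@0.02@0.01	1	
2-phenethylamine	C8H11N	122.096425@0.02@0.01;105.069876@0.02@0.01	1	
octopamine	C8H11NO2	154.086255@0.02@0.01;136.075690@0.02@0.01	1	
norepinephrine	C8H11NO3	170.081169@0.02@0.01;152.070604@0.02@0.01	1	
epinephrine	C9H13NO3	184.096819@0.02@0.01;166.086254@0.02@0.01	1	
normetanephrine	C9H13NO3	184.096819@0.02@0.01;166.086254@0.02@0.01	1	
metanephrine	C10H15NO3	198.112469@0.02@0.01;180.101904@0.02@0.01	1	
5-methoxytryptamine	C11H14N2O	191.117889@0.02@0.01;173.107324@0.02@0.01	1	
kynurenine	C10H12N2O3	209.092068@0.02@0.01;191.081503@0.02@0.01	1	
glutathione	C10H17N3O6S	308.091082@0.02@0.01;290.080517@0.02@0.01	1	
thyroxine	C15H11I4NO4	777.693971@0.02@0.01;759.683406@0.02@0.01	1	
liothyronine	C15H12I3NO4	651.797324@0.02@0.01;633.786759@0.02@0.01	1	
3-iodothyronamine	C14H14INO2	356.014202@0.02@0.01;338.003637@0.02@0.01	1	
thyronamine	C14H15NO2	230.117555@0.02@0.01;212.106990@0.02@0.01	1	
anthranilic acid	C7H7NO2	138.054954@0.02@0.01;120.044389@0.02@0.01	1	
3-hydroxyanthranilic acid	C7H7NO3	154.049869@0.02@0.01;136.039304@0.02@0.01	1	
4-aminobenzoic acid	C7H7NO2	138.054954@0.02@0.01;120.044389@0.02@0.01	1	
glucosamine	C6H13NO5	180.086649@0.02@0.01;162.076084@0.02@0.01	1	
5-hydroxytryptophan	C11H12N2O3	221.092068@0.02@0.01;203.081503@0.02@0.01	1	
DOPA	C9H11NO4	198.076084@0.02@0.01;180.065519@0.02@0.01	1	
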