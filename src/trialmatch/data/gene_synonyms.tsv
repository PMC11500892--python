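# variant	canonical
chek2	chk2
chk2	chk2
erbb2	her2
her2	her2
arid1a mut	arid1a
atm mut	atm
atr mut	atr
brca1 mut	brca1
brca2 mut	brca2
palb2 mut	palb2
rad51 mut	rad51
rad51b mut	rad51b
rad54l mut	rad54l
chk2 mut	chk2
chek2 mut	chk2
tp53 mut	tp53
kras mut	kras
nras mut	nras
egfr mut	egfr
pik3ca mut	pik3ca
mlh1 mut	mlh1
msh2 mut	msh2
brip1 mut	brip1
bard1 mut	bard1
cdk12 mut	cdk12
fgfr2 mut	fgfr2
idh1 mut	idh1
braf mut	braf
fanca mut	fanca
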