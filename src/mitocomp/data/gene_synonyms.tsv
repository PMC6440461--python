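# mitocomp gene-name synonym table, v1
# raw-label (lower-case, spaces removed, '_' -> '-')	canonical token
# protein-coding genes
coi	cox1
co1	cox1
cox-1	cox1
coxi	cox1
cytochromecoxidasesubuniti	cox1
cytochromecoxidasesubunit1	cox1
coii	cox2
co2	cox2
cox-2	cox2
coxii	cox2
cytochromecoxidasesubunitii	cox2
cytochromecoxidasesubunit2	cox2
coiii	cox3
co3	cox3
cox-3	cox3
coxiii	cox3
cytochromecoxidasesubunitiii	cox3
cytochromecoxidasesubunit3	cox3
nd1	nad1
ndh1	nad1
nadh1	nad1
nadhdehydrogenasesubunit1	nad1
nd2	nad2
ndh2	nad2
nadh2	nad2
nadhdehydrogenasesubunit2	nad2
nd3	nad3
nadh3	nad3
nadhdehydrogenasesubunit3	nad3
nd4	nad4
nadh4	nad4
nadhdehydrogenasesubunit4	nad4
nd4l	nad4l
nadh4l	nad4l
nadhdehydrogenasesubunit4l	nad4l
nd5	nad5
nadh5	nad5
nadhdehydrogenasesubunit5	nad5
nd6	nad6
nadh6	nad6
nadhdehydrogenasesubunit6	nad6
cytb	cob
cob	cob
cytochromeb	cob
atpase6	atp6
atp-6	atp6
atpsynthasef0subunit6	atp6
atpase8	atp8
atp-8	atp8
atpsynthasef0subunit8	atp8
# ribosomal RNAs
12s	rrnS
12srrna	rrnS
12sribosomalrna	rrnS
s-rrna	rrnS
srrna	rrnS
smallsubunitribosomalrna	rrnS
rrn12	rrnS
16s	rrnL
16srrna	rrnL
16sribosomalrna	rrnL
l-rrna	rrnL
lrrna	rrnL
largesubunitribosomalrna	rrnL
rrn16	rrnL
# control region
d-loop	CR
dloop	CR
controlregion	CR
a+t-richregion	CR
at-richregion	CR
atrichregion	CR
# tRNAs (full names; duplicated Leu/Ser resolved by anticodon)
trna-ala	trnA
trnaala	trnA
trna-arg	trnR
trnaarg	trnR
trna-asn	trnN
trnaasn	trnN
trna-asp	trnD
trnaasp	trnD
trna-cys	trnC
trnacys	trnC
trna-gln	trnQ
trnagln	trnQ
trna-glu	trnE
trnaglu	trnE
trna-gly	trnG
trnagly	trnG
trna-his	trnH
trnahis	trnH
trna-ile	trnI
trnaile	trnI
trna-lys	trnK
trnalys	trnK
trna-met	trnM
trnamet	trnM
trna-phe	trnF
trnaphe	trnF
trna-pro	trnP
trnapro	trnP
trna-thr	trnT
trnathr	trnT
trna-trp	trnW
trnatrp	trnW
trna-tyr	trnY
trnatyr	trnY
trna-val	trnV
trnaval	trnV
trna-leu	trnL
trnaleu	trnL
trnl	trnL
trna-leu(cun)	trnL1
trna-leu(uur)	trnL2
trna-ser	trnS
trnaser	trnS
trns	trnS
trna-ser(agn)	trnS1
trna-ser(ucn)	trnS2
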