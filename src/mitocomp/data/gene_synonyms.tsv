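#version	1
# alias	canonical
# aliases are matched after lowercasing and stripping spaces, hyphens and underscores
coi	cox1
co1	cox1
coxi	cox1
cox1	cox1
cytochromecoxidasesubuniti	cox1
cytochromecoxidasesubunit1	cox1
cytochromeoxidasesubunit1	cox1
coii	cox2
co2	cox2
coxii	cox2
cox2	cox2
cytochromecoxidasesubunitii	cox2
cytochromecoxidasesubunit2	cox2
cytochromeoxidasesubunit2	cox2
coiii	cox3
co3	cox3
coxiii	cox3
cox3	cox3
cytochromecoxidasesubunitiii	cox3
cytochromecoxidasesubunit3	cox3
cytochromeoxidasesubunit3	cox3
nd1	nad1
nad1	nad1
nadhdehydrogenasesubunit1	nad1
nd2	nad2
nad2	nad2
nadhdehydrogenasesubunit2	nad2
nd3	nad3
nad3	nad3
nadhdehydrogenasesubunit3	nad3
nd4	nad4
nad4	nad4
nadhdehydrogenasesubunit4	nad4
nd4l	nad4L
nad4l	nad4L
nadhdehydrogenasesubunit4l	nad4L
nd5	nad5
nad5	nad5
nadhdehydrogenasesubunit5	nad5
nd6	nad6
nad6	nad6
nadhdehydrogenasesubunit6	nad6
atp6	atp6
atpase6	atp6
atpsynthasef0subunit6	atp6
atpsynthasesubunit6	atp6
atp8	atp8
atpase8	atp8
atpsynthasef0subunit8	atp8
atpsynthasesubunit8	atp8
cytb	cob
cob	cob
cytochromeb	cob
cytochromebapoenzyme	cob
12s	rrnS
12srrna	rrnS
12sribosomalrna	rrnS
srrna	rrnS
smallsubunitribosomalrna	rrnS
rrns	rrnS
16s	rrnL
16srrna	rrnL
16sribosomalrna	rrnL
lrrna	rrnL
largesubunitribosomalrna	rrnL
rrnl	rrnL
controlregion	CR
dloop	CR
atrichregion	CR
putativecontrolregion	CR
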