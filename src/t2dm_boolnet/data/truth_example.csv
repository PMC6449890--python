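# Example literature truth table (a curation assembled by this package
# from published up/down annotations of the modeled interactions under
# T2DM stress conditions; the original study did not publish its truth
# labels, so validation runs against this file are illustrative and are
# not expected to reproduce the study's averaged metric values).
# schema: gene,expected,source_citation
gene,expected,source_citation
IRE1,1,"UPR sensor active under unresolved ER stress"
XBP1,1,"downstream of IRE1 in beta-cell dysfunction"
JNK,1,"activated by IRE1/TRAF2/ASK1 and oxidative stress"
BCL2,0,"anti-apoptotic; inhibited by JNK and CHOP"
BAX,1,"pro-apoptotic; de-repressed when BCL2 is low"
BAK,1,"pro-apoptotic; de-repressed when BCL2 is low"
ATF4,1,"induced via EIF2S1 phosphorylation under ER stress"
CHOP,1,"pro-apoptotic ER-stress effector"
ASK1,1,"activated by oxidative stress and TRAF2"
p38,1,"activated by oxidative stress; elevates CHOP"
CASP8,1,"initiator caspase downstream of FADD/RAIDD"
CASP9,1,"initiator caspase downstream of the apoptosome"
CASP3,1,"effector caspase executing apoptosis"
XIAP,0,"caspase inhibitor; antagonized by DIABLO and HtrA2"
DIABLO,1,"XIAP antagonist released from mitochondria"
HtrA2,1,"XIAP antagonist released from mitochondria"
CytochromeC,1,"released upon BAX/BAK pore formation"
APAF1,1,"apoptosome scaffold downstream of cytochrome c"
Apoptosis,1,"beta-cell apoptosis under sustained stress"
IRS,0,"inhibited by JNK, S6K, SOCS3 and IKK-beta in insulin resistance"
GLUT4,1,"glucose transporter; partial activity retained"
mTORC1,1,"hyperactive mTORC1/S6K signaling in T2DM"
S6K,1,"hyperactive mTORC1/S6K signaling in T2DM"
FOXO1,0,"suppressed by residual AKT activity"
PEPCK,0,"follows FOXO1 suppression"
G6PC,0,"follows FOXO1 suppression"
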