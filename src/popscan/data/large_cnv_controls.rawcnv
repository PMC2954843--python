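# Large (>500 kb) CNV calls, control group (197 samples). Lengths are the
# calling tool's printed lengths (bp); coordinates 1-based inclusive.
chr2:836164-1827317 numsnp=202 length=991,000 state5,cn=3 Aut_26 startsnp=rs4533500 endsnp=rs11127313
chr3:186745-1313259 numsnp=339 length=1,127,000 state5,cn=3 Aut_46 startsnp=rs6442427 endsnp=rs1353825
chr3:57010-1122201 numsnp=267 length=1,065,000 state5,cn=3 Aut_99 startsnp=rs1516321 endsnp=rs6797539
chr4:188763338-190322725 numsnp=333 length=1,559,000 state2,cn=1 Aut_37 startsnp=rs13147499 endsnp=rs13106777
chr4:190385789-190982886 numsnp=69 length=597,000 state5,cn=3 Aut_141 startsnp=rs10446846 endsnp=rs6844114
chr5:104486852-105008254 numsnp=58 length=521,000 state5,cn=3 Aut_36 startsnp=rs294152 endsnp=rs6872786
chr7:49000866-49879997 numsnp=165 length=879,000 state5,cn=3 Aut_203 startsnp=rs1004168 endsnp=rs6963083
chr7:79347222-81014740 numsnp=336 length=1,668,000 state2,cn=1 Aut_65 startsnp=rs6949571 endsnp=rs2909580
chr8:4005541-4886423 numsnp=781 length=881,000 state2,cn=1 Aut_38 startsnp=rs7006672 endsnp=rs7815159
chr8:85925158-87860757 numsnp=257 length=1,936,000 state2,cn=1 Aut_114 startsnp=rs4740033 endsnp=rs11781187
chr9:22934927-23536461 numsnp=136 length=602,000 state5,cn=3 Aut_54 startsnp=rs1463014 endsnp=rs7028484
chr12:33415349-34701470 numsnp=104 length=1,286,000 state6,cn=4 Aut_39 startsnp=rs1905414 endsnp=rs9706509
chr15:70783089-73316235 numsnp=382 length=2,533,000 state5,cn=3 Aut_10 startsnp=rs11072382 endsnp=rs1565496
chr16:76525505-77164850 numsnp=235 length=639,000 state5,cn=3 Aut_148 startsnp=rs387138 endsnp=rs2346008
chr22:17690812-18613429 numsnp=248 length=923,000 state5,cn=3 Aut_94 startsnp=rs982520 endsnp=rs854971
chr22:19102598-19665559 numsnp=97 length=563,000 state5,cn=3 Aut_94 startsnp=rs738089 endsnp=rs7292968
chrX:6468166-8112188 numsnp=190 length=1,644,000 state5,cn=3 Aut_157 startsnp=rs6654819 endsnp=rs2278935
chrX:93063380-93732495 numsnp=88 length=669,000 state1,cn=0 Aut_155 startsnp=rs6615574 endsnp=rs5950049
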