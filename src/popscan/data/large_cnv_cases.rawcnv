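# Large (>500 kb) CNV calls, case group (103 samples). Lengths are the
# calling tool's printed lengths (bp); coordinates 1-based inclusive.
chr1:144943150-145824905 numsnp=207 length=882,000 state5,cn=3 AC0037 startsnp=rs6656361 endsnp=rs11240147
chr2:129716352-130250751 numsnp=114 length=534,000 state2,cn=1 AC0068 startsnp=rs1251175 endsnp=rs7578253
chr2:199943597-201740672 numsnp=324 length=1,797,000 state2,cn=1 AC0086 startsnp=rs13028839 endsnp=rs10200857
chr4:189924391-191164126 numsnp=174 length=1,240,000 state2,cn=1 AC0025 startsnp=rs4863387 endsnp=rs13120250
chr7:124752465-125591197 numsnp=132 length=839,000 state2,cn=1 AC0058 startsnp=rs7810309 endsnp=rs510319
chr7:78246495-97499079 numsnp=3381 length=18,681,000 state5,cn=3 AC0015 startsnp=rs13308578 endsnp=rs6960808
chr10:41756307-42461241 numsnp=49 length=705,000 state5,cn=3 AC0061 startsnp=rs10909011 endsnp=rs158389
chr10:54450683-58765948 numsnp=951 length=4,315,000 state2,cn=1 AC0045 startsnp=rs2249349 endsnp=rs2928464
chr11:124367724-134445626 numsnp=2842 length=10,078,000 state2,cn=1 AC0052 startsnp=rs6590113 endsnp=rs11224228
chr12:37835456-42584684 numsnp=976 length=4,538,000 state5,cn=3 AC0093 startsnp=rs11170890 endsnp=rs4488262
chr16:15032942-16197033 numsnp=201 length=1,164,000 state5,cn=3 AC0003 startsnp=rs4985124 endsnp=rs8056397
chr16:21482719-29234430 numsnp=1266 length=7,175,000 state5,cn=3 AC0088 startsnp=rs13339281 endsnp=rs7500911
chr17:28980655-29960126 numsnp=350 length=979,000 state5,cn=3 AC0100 startsnp=rs11657037 endsnp=rs11657603
chr22:48833840-49524956 numsnp=126 length=691,000 state2,cn=1 AC0058 startsnp=rs137916 endsnp=rs2285395
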