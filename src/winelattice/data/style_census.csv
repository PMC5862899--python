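year,chenin_unwooded_dry,chenin_wooded_dry,chenin_semi_dry,sauvignon_unwooded_dry,sauvignon_wooded_dry
2008,210,94,32,514,20
2009,207,110,40,544,24
2010,212,117,42,572,32
2011,201,113,66,592,34
2012,209,122,77,614,45
2013,225,137,79,632,52
2014,224,157,72,612,65
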