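varietal,attribute,citations
sauvignon_blanc,Mineral,662
sauvignon_blanc,Tropical,660
sauvignon_blanc,Grass,581
sauvignon_blanc,Gooseberry,378
sauvignon_blanc,Fig,349
sauvignon_blanc,Lime,292
sauvignon_blanc,Fruity,262
sauvignon_blanc,Passionfruit,240
sauvignon_blanc,Green,234
sauvignon_blanc,Flint,205
sauvignon_blanc,Green pepper,195
sauvignon_blanc,Asparagus,192
sauvignon_blanc,Grapefruit,188
sauvignon_blanc,Nettle,175
sauvignon_blanc,Herbaceous,171
sauvignon_blanc,Apple,167
sauvignon_blanc,Lemon,155
sauvignon_blanc,Dust,143
sauvignon_blanc,Capsicum,128
sauvignon_blanc,Citrus fruit,124
sauvignon_blanc,Steely,110
sauvignon_blanc,Melon,108
sauvignon_blanc,Pineapple,106
sauvignon_blanc,Herbal,103
sauvignon_blanc,Greengage,95
sauvignon_blanc,Leaves,90
sauvignon_blanc,Lemongrass,88
sauvignon_blanc,Herbs,88
sauvignon_blanc,Granadilla,83
sauvignon_blanc,Pear,81
sauvignon_blanc,Fynbos,81
sauvignon_blanc,Blackcurrant,80
sauvignon_blanc,Savoury,77
sauvignon_blanc,Pithy,66
sauvignon_blanc,Khaki Bush,60
sauvignon_blanc,Guava,54
sauvignon_blanc,Oak,53
sauvignon_blanc,Green peas,52
sauvignon_blanc,Floral,52
chenin_blanc,Oak,553
chenin_blanc,Acid/Acidity,525
chenin_blanc,Apple,440
chenin_blanc,Fresh,395
chenin_blanc,Tropical,307
chenin_blanc,Dry,300
chenin_blanc,Fruit,297
chenin_blanc,Ripe fruit,283
chenin_blanc,Rich,263
chenin_blanc,Melon,242
chenin_blanc,Crisp,232
chenin_blanc,Balance,214
chenin_blanc,Peach,183
chenin_blanc,Honey,172
chenin_blanc,Light,168
chenin_blanc,Pear,149
chenin_blanc,Lees characteristics,148
chenin_blanc,Pineapple,136
chenin_blanc,Floral,131
chenin_blanc,Lime,113
chenin_blanc,Thatch,111
chenin_blanc,Mineral,107
chenin_blanc,Sweet,106
chenin_blanc,Citrus,102
chenin_blanc,Complex,100
chenin_blanc,Creamy,97
chenin_blanc,Spice,97
chenin_blanc,Semi-dry,93
chenin_blanc,Apricot,92
chenin_blanc,Lemon,86
chenin_blanc,Quince,85
chenin_blanc,Juicy,84
chenin_blanc,Round,80
chenin_blanc,Vanilla,77
chenin_blanc,Full,70
chenin_blanc,Savoury,68
chenin_blanc,Nuts,63
chenin_blanc,Guava,62
chenin_blanc,Almond,52
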