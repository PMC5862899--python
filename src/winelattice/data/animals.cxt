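B

8
9

Leach
Bream
Frog
Dog
Spike-weed
Reed
Bean
Maize
needs water
lives in water
lives on land
needs chlorophyll
1-leaf germination
2-leaf germination
is motile
has limbs
suckles young
XX.......
XX....X..
XXX...XX.
X.X...XXX
XX.XX....
XXXXX....
X.XX.X...
X.XXX....
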