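{
  "synonyms": {
    "green apple": "apple",
    "ripe apple": "apple",
    "golden delicious apple": "apple",
    "granny smith apple": "apple",
    "fleshy apple": "apple",
    "crisp apple": "apple",
    "apple fruit salad": "apple",
    "bruised apple": "apple",
    "yellow apple": "apple",
    "red apple": "apple",
    "apple": "apple",
    "bubblegum": "bubblegum",
    "bubblegum hint": "bubblegum",
    "bubblegummy": "bubblegum",
    "styling peach": "peach",
    "peach concentration": "peach",
    "peach nuances": "peach",
    "peach flavours": "peach",
    "peach kernel": "peach",
    "peachy": "peach",
    "flush": "peach",
    "sweet-ripe": "peach",
    "peachiness": "peach",
    "peach toned": "peach",
    "gentle peach": "peach",
    "sun ripe peach": "peach",
    "peach": "peach",
    "uncomplicated grass": "grass",
    "whafty grass": "grass",
    "dusty grass": "grass",
    "dry grass": "grass",
    "grassy": "grass",
    "grass": "grass",
    "perfumed citrus": "citrus",
    "citrus notes": "citrus",
    "citrus flavours": "citrus",
    "citrus peel": "citrus",
    "citrus intensity": "citrus",
    "citrus concentration": "citrus",
    "citrus zest": "citrus",
    "fine citrus": "citrus",
    "lively citrus": "citrus",
    "citrus": "citrus",
    "lees": "lees characteristics",
    "leesy": "lees characteristics",
    "sur lie": "lees characteristics",
    "lees treatment": "lees characteristics",
    "passion fruit": "passionfruit",
    "passionfruit": "passionfruit",
    "granadilla": "granadilla",
    "acidity": "acid",
    "acid": "acid",
    "complexity": "complex",
    "complex": "complex",
    "oaky": "oak",
    "oaked": "oak",
    "oak": "oak",
    "minerality": "mineral",
    "mineral": "mineral",
    "honeyed": "honey",
    "honey": "honey",
    "earthiness": "earthy",
    "earthy": "earthy",
    "gooseberries": "gooseberry",
    "gooseberry": "gooseberry",
    "tropical": "tropical",
    "apricot": "apricot",
    "vanilla": "vanilla",
    "nuts": "nuts",
    "nutty": "nuts",
    "spice": "spice",
    "spicy": "spice",
    "sweet": "sweet",
    "semi-dry": "semi-dry",
    "biscuit": "biscuit",
    "thatch": "thatch",
    "quince": "quince",
    "capsicum": "capsicum",
    "gunpowder": "gunpowder",
    "asparagus": "asparagus",
    "nettle": "nettle",
    "nettles": "nettle",
    "pineapple": "pineapple",
    "guava": "guava",
    "melon": "melon",
    "blackcurrant": "blackcurrant",
    "fresh": "fresh",
    "rich": "rich",
    "balance": "balance",
    "balanced": "balance",
    "fruit": "fruit",
    "fruity": "fruit",
    "crisp": "crisp",
    "light": "light",
    "dry": "dry",
    "floral": "floral",
    "pear": "pear",
    "lemon": "lemon",
    "lime": "lime",
    "juicy": "juicy",
    "round": "round",
    "full": "full",
    "savoury": "savoury",
    "creamy": "creamy",
    "almond": "almond"
  },
  "stopwords": [
    "the", "a", "an", "and", "but", "with", "of", "to", "on", "in", "for",
    "from", "this", "that", "is", "are", "was", "were", "it", "its", "at",
    "by", "as", "up", "still", "will", "all", "some", "very", "so", "has",
    "have", "be", "or", "also", "too", "when", "then", "than", "here"
  ],
  "nonsensory": [
    "perfect for summer lunches", "ideal for picnics", "summer wine",
    "easy going", "quaffer", "opens", "shy", "delicious", "notes", "aromas",
    "nuances", "flavours", "hints", "hint", "palate", "nose", "finish",
    "prominent", "integrate", "vineyards", "vineyard", "soil types",
    "ripeness levels", "artfully blended", "blended", "well made",
    "food friendly", "braai companion", "great value", "everyday drinking",
    "crowd pleaser", "versatile", "approachable", "charming", "well priced",
    "early drinking", "good now", "keep a year", "party starter",
    "different", "four", "three", "two", "one", "levels", "types"
  ],
  "bigrams": [
    "ripe fruit", "citrus fruit", "green pepper", "green peas",
    "lees characteristics", "khaki bush"
  ],
  "connotation_rules": [
    {"descriptor": "oak", "kind": "ALWAYS_KEEP", "cues": ["nose", "palate"]},
    {"descriptor": "balance", "kind": "ALWAYS_KEEP", "cues": []},
    {"descriptor": "acid", "kind": "NEGATION_DROP",
     "cues": ["lacking", "lacks", "lack", "low", "short", "needs", "needing"]},
    {"descriptor": "fruit", "kind": "NEGATION_DROP",
     "cues": ["more", "less", "compared", "previous"]},
    {"descriptor": "fresh", "kind": "STANDALONE_ONLY", "cues": []},
    {"descriptor": "rich", "kind": "STANDALONE_ONLY", "cues": []}
  ]
}
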