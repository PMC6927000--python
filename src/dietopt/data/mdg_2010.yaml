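# MDG 2010 food-group serving bounds (pregnant women follow the adult food
# pyramid) plus palatability bounds on sugar, salt and oil.  [lower, upper]
# in servings per day.  Serving definitions: 30 g carbohydrate for cereals,
# 5 g carbohydrate for sugar, 14 g protein for meat/poultry and fish,
# 7 g protein for legumes and milk, 9 g fat for oil.
"cereals and grains": [4, 8]
"fruits": [2, 3]
"vegetables": [3, 5]
"meat/poultry": [0.5, 2]
"fish": [1, 3]
"legumes": [0.5, 1]
"milk and dairy products": [1, 3]
"sugar": [1, 4]
"salt": [1, 4]
"oil": [1, 4]
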