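fine	middle	coarse
meatball	red meat	meat
beef steak	red meat	meat
pork chop	red meat	meat
chicken breast	poultry	meat
chicken nuggets	poultry	meat
white bread	bread	cereals and potatoes
wholegrain bread	bread	cereals and potatoes
boiled potatoes	potatoes	cereals and potatoes
french fries	potatoes	cereals and potatoes
mashed potatoes	potatoes	cereals and potatoes
tap water	drinks	liquids
orange juice	drinks	liquids
whole milk	drinks	liquids
cola	drinks	liquids
chocolate cake	cake	dessert
apple pie	cake	dessert
apple	fruit	fruits vegetables nuts
banana	fruit	fruits vegetables nuts
olive oil	oils and nuts	fruits vegetables nuts
almonds	oils and nuts	fruits vegetables nuts
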