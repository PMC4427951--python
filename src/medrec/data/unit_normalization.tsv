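# attribute-comparison normalization: surface form <TAB> canonical form
milligram	mg
milligrams	mg
milliliter	ml
milliliters	ml
microgram	mcg
micrograms	mcg
gram	g
grams	g
tabs	tab
tablets	tablet
caps	capsule
capsules	capsule
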