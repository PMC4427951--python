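# Tokens ignored when extracting medication terms from a mention or a
# prescription name: units, dose forms, routes and frequency words.
# One token per line; lines starting with '#' are comments.
# units
mg
ml
mcg
g
# dose forms
tab
tablet
capsule
solution
gel
suspension
nebulizer
powder
syrup
cream
patch
# routes
po
oral
rectal
topical
inhaled
# frequency words
daily
bid
tid
qid
qhs
prn
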