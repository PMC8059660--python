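token	major	place	manner	voicing	height	backness	rounding
p	consonant	labial	stop	voiceless
b	consonant	labial	stop	voiced
t	consonant	alveolar	stop	voiceless
d	consonant	alveolar	stop	voiced
ʈ	consonant	alveolar	stop	voiceless
ɖ	consonant	alveolar	stop	voiced
c	consonant	palatal	stop	voiceless
ɟ	consonant	palatal	stop	voiced
k	consonant	velar	stop	voiceless
g	consonant	velar	stop	voiced
ɡ	consonant	velar	stop	voiced
q	consonant	velar	stop	voiceless
ɢ	consonant	velar	stop	voiced
ʔ	consonant	glottal	stop	voiceless
t͡s	consonant	alveolar	stop	voiceless
d͡z	consonant	alveolar	stop	voiced
t͡ʃ	consonant	palatal	stop	voiceless
d͡ʒ	consonant	palatal	stop	voiced
t͡ɕ	consonant	palatal	stop	voiceless
d͡ʑ	consonant	palatal	stop	voiced
t͡ɬ	consonant	alveolar	stop	voiceless
m	consonant	labial	nasal	voiced
ɱ	consonant	labial	nasal	voiced
n	consonant	alveolar	nasal	voiced
ɳ	consonant	alveolar	nasal	voiced
ɲ	consonant	palatal	nasal	voiced
ŋ	consonant	velar	nasal	voiced
ɴ	consonant	velar	nasal	voiced
ɸ	consonant	labial	continuant	voiceless
β	consonant	labial	continuant	voiced
f	consonant	labial	continuant	voiceless
v	consonant	labial	continuant	voiced
ʋ	consonant	labial	continuant	voiced
θ	consonant	alveolar	continuant	voiceless
ð	consonant	alveolar	continuant	voiced
s	consonant	alveolar	continuant	voiceless
z	consonant	alveolar	continuant	voiced
ʃ	consonant	palatal	continuant	voiceless
ʒ	consonant	palatal	continuant	voiced
ʂ	consonant	alveolar	continuant	voiceless
ʐ	consonant	alveolar	continuant	voiced
ɕ	consonant	palatal	continuant	voiceless
ʑ	consonant	palatal	continuant	voiced
ç	consonant	palatal	continuant	voiceless
ʝ	consonant	palatal	continuant	voiced
x	consonant	velar	continuant	voiceless
ɣ	consonant	velar	continuant	voiced
χ	consonant	velar	continuant	voiceless
ʁ	consonant	velar	continuant	voiced
ħ	consonant	glottal	continuant	voiceless
ʕ	consonant	glottal	continuant	voiced
h	consonant	glottal	continuant	voiceless
ɦ	consonant	glottal	continuant	voiced
ɹ	consonant	alveolar	continuant	voiced
ɻ	consonant	alveolar	continuant	voiced
j	consonant	palatal	continuant	voiced
ɰ	consonant	velar	continuant	voiced
w	consonant	labial	continuant	voiced
ɥ	consonant	labial	continuant	voiced
ʍ	consonant	labial	continuant	voiceless
r	consonant	alveolar	vibrant	voiced
ɾ	consonant	alveolar	vibrant	voiced
ɽ	consonant	alveolar	vibrant	voiced
ʙ	consonant	labial	vibrant	voiced
ʀ	consonant	velar	vibrant	voiced
l	consonant	alveolar	lateral	voiced
ɭ	consonant	alveolar	lateral	voiced
ʎ	consonant	palatal	lateral	voiced
ʟ	consonant	velar	lateral	voiced
ɬ	consonant	alveolar	lateral	voiceless
ɮ	consonant	alveolar	lateral	voiced
i	vowel				high	front	unrounded
y	vowel				high	front	rounded
ɪ	vowel				high	front	unrounded
ʏ	vowel				high	front	rounded
ɨ	vowel				high	central	unrounded
ʉ	vowel				high	central	rounded
ɯ	vowel				high	back	unrounded
u	vowel				high	back	rounded
ʊ	vowel				high	back	rounded
e	vowel				mid	front	unrounded
ø	vowel				mid	front	rounded
ɛ	vowel				mid	front	unrounded
œ	vowel				mid	front	rounded
ɘ	vowel				mid	central	unrounded
ə	vowel				mid	central	unrounded
ɵ	vowel				mid	central	rounded
ɜ	vowel				mid	central	unrounded
ɞ	vowel				mid	central	rounded
ɤ	vowel				mid	back	unrounded
o	vowel				mid	back	rounded
ʌ	vowel				mid	back	unrounded
ɔ	vowel				mid	back	rounded
æ	vowel				low	front	unrounded
a	vowel				low	front	unrounded
ɶ	vowel				low	front	rounded
ɐ	vowel				low	central	unrounded
ɑ	vowel				low	back	unrounded
ɒ	vowel				low	back	rounded
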