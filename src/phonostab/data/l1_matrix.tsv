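axis	value	coding
place	labial	earlier
place	alveolar	earlier
place	palatal	later
place	velar	later
place	glottal	later
manner	stop	earlier
manner	continuant	later
voicing	voiceless	earlier
voicing	voiced	later
openness	low	earlier
openness	high	later
openness	mid	later
backness	back	earlier
backness	front	later
backness	central	later
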