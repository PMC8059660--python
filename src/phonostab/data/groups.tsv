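name	feature_class	major	predicate
voiced	voicing	consonant	voicing=voiced
voiceless	voicing	consonant	voicing=voiceless
nasal	manner	consonant	manner=nasal
stop	manner	consonant	manner=stop
continuant	manner	consonant	manner=continuant
vibrant	manner	consonant	manner=vibrant
lateral	manner	consonant	manner=lateral
voiced nasal	manner×voicing	consonant	manner=nasal;voicing=voiced
voiceless nasal	manner×voicing	consonant	manner=nasal;voicing=voiceless
voiced stop	manner×voicing	consonant	manner=stop;voicing=voiced
voiceless stop	manner×voicing	consonant	manner=stop;voicing=voiceless
voiced continuant	manner×voicing	consonant	manner=continuant;voicing=voiced
voiceless continuant	manner×voicing	consonant	manner=continuant;voicing=voiceless
voiced vibrant	manner×voicing	consonant	manner=vibrant;voicing=voiced
voiceless vibrant	manner×voicing	consonant	manner=vibrant;voicing=voiceless
voiced lateral	manner×voicing	consonant	manner=lateral;voicing=voiced
voiceless lateral	manner×voicing	consonant	manner=lateral;voicing=voiceless
labial	place	consonant	place=labial
alveolar	place	consonant	place=alveolar
palatal	place	consonant	place=palatal
velar	place	consonant	place=velar
glottal	place	consonant	place=glottal
voiced labial	place×voicing	consonant	place=labial;voicing=voiced
voiceless labial	place×voicing	consonant	place=labial;voicing=voiceless
voiced alveolar	place×voicing	consonant	place=alveolar;voicing=voiced
voiceless alveolar	place×voicing	consonant	place=alveolar;voicing=voiceless
voiced palatal	place×voicing	consonant	place=palatal;voicing=voiced
voiceless palatal	place×voicing	consonant	place=palatal;voicing=voiceless
voiced velar	place×voicing	consonant	place=velar;voicing=voiced
voiceless velar	place×voicing	consonant	place=velar;voicing=voiceless
voiced glottal	place×voicing	consonant	place=glottal;voicing=voiced
voiceless glottal	place×voicing	consonant	place=glottal;voicing=voiceless
high vowel	height	vowel	height=high
mid vowel	height	vowel	height=mid
low vowel	height	vowel	height=low
front vowel	backness	vowel	backness=front
central vowel	backness	vowel	backness=central
back vowel	backness	vowel	backness=back
rounded vowel	rounding	vowel	rounding=rounded
unrounded vowel	rounding	vowel	rounding=unrounded
high front vowel	height×backness	vowel	height=high;backness=front
high central vowel	height×backness	vowel	height=high;backness=central
high back vowel	height×backness	vowel	height=high;backness=back
mid front vowel	height×backness	vowel	height=mid;backness=front
mid central vowel	height×backness	vowel	height=mid;backness=central
mid back vowel	height×backness	vowel	height=mid;backness=back
low front vowel	height×backness	vowel	height=low;backness=front
low central vowel	height×backness	vowel	height=low;backness=central
low back vowel	height×backness	vowel	height=low;backness=back
front rounded vowel	backness×rounding	vowel	backness=front;rounding=rounded
front unrounded vowel	backness×rounding	vowel	backness=front;rounding=unrounded
back rounded vowel	backness×rounding	vowel	backness=back;rounding=rounded
back unrounded vowel	backness×rounding	vowel	backness=back;rounding=unrounded
low front rounded vowel	height×backness×rounding	vowel	height=low;backness=front;rounding=rounded
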