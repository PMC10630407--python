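afr	Afrikaans
alb	Albanian
amh	Amharic
ara	Arabic
arm	Armenian
aze	Azerbaijani
ben	Bengali
bos	Bosnian
bul	Bulgarian
bur	Burmese
cat	Catalan
chi	Chinese
cze	Czech
dan	Danish
dut	Dutch
eng	English
epo	Esperanto
est	Estonian
fin	Finnish
fre	French
geo	Georgian
ger	German
gla	Scottish Gaelic
gre	Greek, Modern
heb	Hebrew
hin	Hindi
hrv	Croatian
hun	Hungarian
ice	Icelandic
ind	Indonesian
ita	Italian
jpn	Japanese
kin	Kinyarwanda
kor	Korean
lat	Latin
lav	Latvian
lit	Lithuanian
mac	Macedonian
may	Malay
mul	Multiple languages
nor	Norwegian
per	Persian
pol	Polish
por	Portuguese
pus	Pushto
rum	Romanian
rus	Russian
san	Sanskrit
scc	Serbian
slo	Slovak
slv	Slovenian
spa	Spanish
srp	Serbian
swe	Swedish
tha	Thai
tur	Turkish
ukr	Ukrainian
und	Undetermined
urd	Urdu
uzb	Uzbek
vie	Vietnamese
wel	Welsh
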