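# curated English syllable lexicon: word<TAB>syllable_count
a	1
actually	3
answer	2
anxiety	4
area	3
areas	3
audio	3
average	3
beautiful	3
being	2
believe	2
believed	2
business	2
cafe	2
camera	2
carriage	2
cat	1
center	2
centre	2
chocolate	2
climb	1
climbed	1
climbing	2
colleague	2
college	2
comfortable	3
create	2
created	3
curious	3
diet	2
different	3
dog	1
evening	2
every	2
everyone	3
everything	3
experience	4
family	3
favorite	3
favourite	3
february	4
fire	1
flower	2
for	1
garage	2
genre	2
hour	1
i	1
idea	3
ideas	3
image	2
images	3
immediately	5
interest	3
interesting	3
ion	2
iron	2
island	2
karaoke	4
keyboard	2
knowledge	2
language	2
languages	3
library	3
lion	2
literature	4
little	2
machine	2
machines	2
marriage	2
material	4
media	3
medium	3
message	2
messages	3
meter	2
metre	2
minute	2
minutes	2
ocean	2
olympics	3
orange	2
our	1
people	2
period	3
piano	3
poem	2
poetry	3
power	2
probably	3
quiet	2
quote	1
quotes	1
radio	3
really	2
recipe	3
restaurant	3
riot	2
sat	1
science	2
sending	2
serious	3
society	4
suite	1
syllable	3
syllables	3
temperature	4
thanks	1
the	1
theater	2
theatre	2
this	1
towel	2
type	1
typed	1
types	1
typing	2
typist	2
usually	3
variety	4
various	3
vegetable	3
video	3
violet	3
wednesday	2
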