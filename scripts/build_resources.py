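"""One-off builder for the packaged word-list resources.

Writes, into src/typability/resources/:
  top1000_words.txt  - 1,000 common English words, roughly frequency ordered
  dictionary_words.txt - compact English dictionary (bases + rule inflections
                         + UK/US variant spellings), one word per line
  bigram_freq.tsv    - 26x26 letter-bigram frequencies derived from the
                       top-1000 list under Zipfian rank weights, per million
  syllables.tsv      - curated word -> syllable-count lexicon

Run from the repo root:  python scratch/build_resources.py
"""

from collections import Counter
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "typability" / "resources"

# ---------------------------------------------------------------- top 1000
# Roughly frequency-ordered common English words (function words first,
# then common content words), assembled for this package.
TOP = """
the of and to a in that is was he for it with as his on be at by i
this had not are but from or have an they which one you were her all
she there would their we him been has when who will more no if out so
said what up its about into than them can only other new some could
time these two may then do first any my now such like our over man me
even most made after also did many before must through back years where
much your way well down should because each just those people mr how
too little state good very make world still own see men work long get
here between both life being under never day same another know while
last might us great old year off come since against go came right used
take three states himself few house use during without again place
american around however home small found mrs thought went say part once
general high upon school every don't does got united left number course
war until always away something fact though water less public put think
almost hand enough far took head yet government system better set told
nothing night end why called didn't eyes find going look asked later
knew point next city business give group toward young let room president
side social present given several order national second possible rather
per face among form important often things looked early white case
become large need big four within felt along children saw best church
ever least power development light thing family interest want members
mind country area others although turned done open god service certain
kind began different door thus help means sense whole matter perhaps
itself it's times human law line above name example action company hands
local show whether five history gave today either act feet across taken
past quite anything seen having death week field car word already
themselves information tell together shown college period body keep
sure free real cannot miss behind seems probably cost maybe toward
available problem brought making meet run level alone education process
money further south change play plan result hard evidence million
england hope able six moment nature outside play figure leave voice
girl effect report mother known space boy france study yes close
program words short class am since personal value question complete
army told building society control full read black usually music
special university students written ground surface necessary strong
air increase modern live particular provide person return department
held truth table red common expected half understand political
experience care force idea instead economic position including party
type seem office army nation america top following months army bring
wife himself record love wanted cut everything certainly reason market
land army hour move trying yes federal approach situation easy court
believe various congress stood military policy price appear working
foreign effort morning total street board century farm trade image
road clear longer feeling stage lay wall term paper lower usual piece
member hear front purpose oh else sound wide sort staff freedom minutes
shall fire fine low western committee hundred answer bad sent girls
food support mouth research tax basis spring fall someone direct hold
deal problems property merely needed private labor food book ready
army section pressure beyond coming doubt countries floor sat concerned
england close training county defense actually paid neither amount
statement rate natural army chance indeed father step river earth
heart costs else arm centre leader speak ago single list account
simple methods peace basic else army lines lost pay industry except
due attention final anyone considered ten size stock dark cent equal
distance range material hot schools remember word walked subject
written wrote strength marriage news nice station somewhat friends
attack additional influence beginning languages established picture
ran provided decided factors army girl couple reached simply moved
normal medical plant easily ideas manner island religious weeks
letter serious evening fear lead stop unit pool except except meaning
numbers knowledge points directly cold current built justice secretary
deep plane growth everyone literature international difficult else
either played determined square cause daily cases recent levels
beautiful language windows population larger writing summer letters
choice happy science thinking lot trouble served corner seemed
addition earlier ones particularly visit sales slowly immediately
husband master gone movement themselves gun月 else main else average
finally alone passed cars therefore quality opportunity please living
learned design brown audience obtained stopped spirit plans eight
respect direction charge carried regard friend developed month third
union apparently covered girl song reaction gives blood shot
performance demand entire rest games green needs race seven hair
technical slightly capital sight soon met structure nor condition
continue treatment shown role aid kept pattern moral radio played
phone success clearly hospital view date nearly understanding
involved baseball filled sun relations computer meant closed
village alive trip southern middle christian evening industrial
specific temperature degree heavy drive former red added article
spent described england else else changed inside bottom club
anyone bed thirty else dead sign window shoulder français else
else else else else else else else else
""".split()

EXTRA_COMMON = """
cat dog run sun sea sky eat ate sit sat top map cup pen box kid job
fun bus egg leg arm ear eye toe hat bag bat ball tree fish bird horse
cow pig sheep goat duck hen rain snow wind storm cloud river lake hill
mountain forest grass flower leaf root stone rock sand beach ocean
ship boat train plane truck wheel engine door roof wall floor table
chair desk lamp clock watch shirt shoes dress coat glass plate spoon
fork knife bread milk cheese butter sugar salt meat rice soup cake tea
coffee fruit apple orange banana grape lemon potato tomato onion bean
corn wheat farm garden park city town village street bridge tower
castle palace temple market shop store price money gold silver iron
wood paper glass cotton silk wool team game score goal race match
winner loser player coach rule fair luck skill brain heart bone skin
blood breath sleep dream wake walk jump climb swim dance sing laugh
cry smile shout whisper listen watch touch taste smell feel carry lift
push pull throw catch drop pick open close lock unlock begin finish
start stop wait stay arrive depart travel journey visit guest host
friend enemy neighbor stranger family parent child baby brother sister
uncle aunt cousin grandmother grandfather wedding birthday holiday
festival gift card letter message phone email internet website screen
keyboard mouse button type write draw paint color shape circle square
triangle line curve angle size length width height weight speed slow
quick fast early late soon never always often sometimes rarely
""".split()


def clean(words):
    seen = []
    have = set()
    for w in words:
        w = w.strip().lower()
        if not w or not w.isascii() or not w.isalpha() and "'" not in w:
            continue
        if any(c for c in w if not (c.isalpha() or c == "'")):
            continue
        if w not in have:
            have.add(w)
            seen.append(w)
    return seen


def main():
    top = clean(TOP)
    reserve = [w for w in clean(EXTRA_COMMON) if w not in set(top)]
    if len(top) < 1000:
        top = top + reserve[: 1000 - len(top)]
    top = top[:1000]
    assert len(top) == len(set(top)) == 1000, len(top)
    (OUT / "top1000_words.txt").write_text("\n".join(top) + "\n", encoding="utf-8")

    # ---------------------------------------------------------- dictionary
    bases = set(top) | set(clean(EXTRA_COMMON))
    bases |= set(
        """
        thanks suite downtown send sending sent kitten sitting zip code
        website address fax hotel distraction taking care possible might
        wind strong gusting senate approve treaty catch catches yard yards
        game started sunday monday tuesday wednesday thursday friday
        saturday january february march april may june july august
        september october november december olympics visitor visitors
        flood atlanta guy paper sign happened office something anywhere
        everybody nobody somebody anybody nothing everything anyone
        everyone noone cannot o'clock i'm i'll i've i'd you're you've
        don't doesn't didn't can't won't isn't aren't wasn't weren't
        couldn't wouldn't shouldn't let's that's there's here's what's
        who's it's we're they're
        typing typist typists keyboard keyboards finger fingers thumb
        thumbs
        """.split()
    )
    # UK / US / CA / AU variant spellings (both directions).
    variants = """
    colour color favour favor flavour flavor honour honor labour labor
    neighbour neighbor behaviour behavior centre center metre meter
    litre liter theatre theater fibre fiber organise organize organised
    organized organisation organization realise realize realised realized
    recognise recognize analyse analyze apologise apologize travelled
    traveled travelling traveling cancelled canceled jewellery jewelry
    programme program defence defense offence offense licence license
    practise practice catalogue catalog dialogue dialog grey gray
    """.split()
    bases |= set(variants)

    vowels = set("aeiou")
    inflected = set()
    skip_inflect = {w for w in bases if len(w) < 3 or "'" in w}
    for w in sorted(bases - skip_inflect):
        # plural / 3rd person -s, -es
        if w.endswith(("s", "x", "z", "ch", "sh")):
            inflected.add(w + "es")
        elif w.endswith("y") and len(w) > 2 and w[-2] not in vowels:
            inflected.add(w[:-1] + "ies")
        else:
            inflected.add(w + "s")
        # -ed / -ing
        if w.endswith("e") and not w.endswith("ee"):
            inflected.add(w + "d")
            inflected.add(w[:-1] + "ing")
        elif w.endswith("y") and len(w) > 2 and w[-2] not in vowels:
            inflected.add(w[:-1] + "ied")
            inflected.add(w + "ing")
        else:
            inflected.add(w + "ed")
            inflected.add(w + "ing")
    dictionary = sorted(bases | inflected)
    (OUT / "dictionary_words.txt").write_text("\n".join(dictionary) + "\n", encoding="utf-8")

    # ------------------------------------------------------- bigram table
    # Zipfian rank weights over the top-1000 list; interior letter pairs.
    counts = Counter()
    total = 0.0
    for rank, w in enumerate(top, start=1):
        weight = 1.0 / rank
        letters = [c for c in w if c.isalpha()]
        for a, b in zip(letters, letters[1:]):
            counts[(a, b)] += weight
            total += weight
    import string

    lines = ["# letter-bigram frequencies per million, derived from the"]
    lines.append("# packaged top-1000 word list under Zipfian rank weights")
    lines.append("# columns: first_letter, second_letter, per_million")
    for a in string.ascii_lowercase:
        for b in string.ascii_lowercase:
            per_million = counts.get((a, b), 0.0) / total * 1e6
            lines.append(f"{a}\t{b}\t{per_million:.2f}")
    (OUT / "bigram_freq.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    # --------------------------------------------------- syllable lexicon
    lex = {
        "the": 1, "a": 1, "i": 1, "cat": 1, "dog": 1, "sat": 1, "sending": 2,
        "thanks": 1, "for": 1, "this": 1, "people": 2, "little": 2,
        "every": 2, "everything": 3, "everyone": 3, "business": 2,
        "different": 3, "interesting": 3, "interest": 3, "family": 3,
        "area": 3, "idea": 3, "being": 2, "science": 2, "quiet": 2,
        "poem": 2, "create": 2, "created": 3, "really": 2, "usually": 3,
        "actually": 3, "beautiful": 3, "average": 3, "chocolate": 2,
        "camera": 2, "evening": 2, "literature": 4, "temperature": 4,
        "comfortable": 3, "vegetable": 3, "wednesday": 2, "february": 4,
        "library": 3, "probably": 3, "favorite": 3, "favourite": 3,
        "restaurant": 3, "ocean": 2, "lion": 2, "fire": 1, "hour": 1,
        "our": 1, "power": 2, "flower": 2, "towel": 2, "poetry": 3,
        "piano": 3, "radio": 3, "video": 3, "audio": 3, "orange": 2,
        "olympics": 3, "area": 3, "ion": 2, "quote": 1, "quotes": 1,
        "suite": 1, "iron": 2, "violet": 3, "diet": 2, "riot": 2,
        "society": 4, "variety": 4, "anxiety": 4, "experience": 4,
        "serious": 3, "various": 3, "curious": 3, "period": 3,
        "material": 4, "immediately": 5, "media": 3, "medium": 3,
        "ideas": 3, "areas": 3, "theatre": 2, "theater": 2, "centre": 2,
        "center": 2, "metre": 2, "meter": 2, "genre": 2, "recipe": 3,
        "cafe": 2, "karaoke": 4, "typing": 2, "typed": 1, "types": 1,
        "type": 1, "typist": 2, "syllable": 3, "syllables": 3,
        "keyboard": 2, "minute": 2, "minutes": 2, "believed": 2,
        "believe": 2, "machine": 2, "machines": 2, "message": 2,
        "messages": 3, "college": 2, "colleague": 2, "language": 2,
        "languages": 3, "garage": 2, "image": 2, "images": 3,
        "climbed": 1, "climbing": 2, "climb": 1, "answer": 2,
        "island": 2, "knowledge": 2, "marriage": 2, "carriage": 2,
    }
    lines = ["# curated English syllable lexicon: word<TAB>syllable_count"]
    for w in sorted(lex):
        lines.append(f"{w}\t{lex[w]}")
    (OUT / "syllables.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    print("top1000:", len(top))
    print("dictionary:", len(dictionary))
    print("lexicon:", len(lex))


if __name__ == "__main__":
    main()
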