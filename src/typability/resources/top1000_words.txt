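the
of
and
to
a
in
that
is
was
he
for
it
with
as
his
on
be
at
by
i
this
had
not
are
but
from
or
have
an
they
which
one
you
were
her
all
she
there
would
their
we
him
been
has
when
who
will
more
no
if
out
so
said
what
up
its
about
into
than
them
can
only
other
new
some
could
time
these
two
may
then
do
first
any
my
now
such
like
our
over
man
me
even
most
made
after
also
did
many
before
must
through
back
years
where
much
your
way
well
down
should
because
each
just
those
people
mr
how
too
little
state
good
very
make
world
still
own
see
men
work
long
get
here
between
both
life
being
under
never
day
same
another
know
while
last
might
us
great
old
year
off
come
since
against
go
came
right
used
take
three
states
himself
few
house
use
during
without
again
place
american
around
however
home
small
found
mrs
thought
went
say
part
once
general
high
upon
school
every
don't
does
got
united
left
number
course
war
until
always
away
something
fact
though
water
less
public
put
think
almost
hand
enough
far
took
head
yet
government
system
better
set
told
nothing
night
end
why
called
didn't
eyes
find
going
look
asked
later
knew
point
next
city
business
give
group
toward
young
let
room
president
side
social
present
given
several
order
national
second
possible
rather
per
face
among
form
important
often
things
looked
early
white
case
become
large
need
big
four
within
felt
along
children
saw
best
church
ever
least
power
development
light
thing
family
interest
want
members
mind
country
area
others
although
turned
done
open
god
service
certain
kind
began
different
door
thus
help
means
sense
whole
matter
perhaps
itself
it's
times
human
law
line
above
name
example
action
company
hands
local
show
whether
five
history
gave
today
either
act
feet
across
taken
past
quite
anything
seen
having
death
week
field
car
word
already
themselves
information
tell
together
shown
college
period
body
keep
sure
free
real
cannot
miss
behind
seems
probably
cost
maybe
available
problem
brought
making
meet
run
level
alone
education
process
money
further
south
change
play
plan
result
hard
evidence
million
england
hope
able
six
moment
nature
outside
figure
leave
voice
girl
effect
report
mother
known
space
boy
france
study
yes
close
program
words
short
class
am
personal
value
question
complete
army
building
society
control
full
read
black
usually
music
special
university
students
written
ground
surface
necessary
strong
air
increase
modern
live
particular
provide
person
return
department
held
truth
table
red
common
expected
half
understand
political
experience
care
force
idea
instead
economic
position
including
party
type
seem
office
nation
america
top
following
months
bring
wife
record
love
wanted
cut
everything
certainly
reason
market
land
hour
move
trying
federal
approach
situation
easy
court
believe
various
congress
stood
military
policy
price
appear
working
foreign
effort
morning
total
street
board
century
farm
trade
image
road
clear
longer
feeling
stage
lay
wall
term
paper
lower
usual
piece
member
hear
front
purpose
oh
else
sound
wide
sort
staff
freedom
minutes
shall
fire
fine
low
western
committee
hundred
answer
bad
sent
girls
food
support
mouth
research
tax
basis
spring
fall
someone
direct
hold
deal
problems
property
merely
needed
private
labor
book
ready
section
pressure
beyond
coming
doubt
countries
floor
sat
concerned
training
county
defense
actually
paid
neither
amount
statement
rate
natural
chance
indeed
father
step
river
earth
heart
costs
arm
centre
leader
speak
ago
single
list
account
simple
methods
peace
basic
lines
lost
pay
industry
except
due
attention
final
anyone
considered
ten
size
stock
dark
cent
equal
distance
range
material
hot
schools
remember
walked
subject
wrote
strength
marriage
news
nice
station
somewhat
friends
attack
additional
influence
beginning
languages
established
picture
ran
provided
decided
factors
couple
reached
simply
moved
normal
medical
plant
easily
ideas
manner
island
religious
weeks
letter
serious
evening
fear
lead
stop
unit
pool
meaning
numbers
knowledge
points
directly
cold
current
built
justice
secretary
deep
plane
growth
everyone
literature
international
difficult
played
determined
square
cause
daily
cases
recent
levels
beautiful
language
windows
population
larger
writing
summer
letters
choice
happy
science
thinking
lot
trouble
served
corner
seemed
addition
earlier
ones
particularly
visit
sales
slowly
immediately
husband
master
gone
movement
main
average
finally
passed
cars
therefore
quality
opportunity
please
living
learned
design
brown
audience
obtained
stopped
spirit
plans
eight
respect
direction
charge
carried
regard
friend
developed
month
third
union
apparently
covered
song
reaction
gives
blood
shot
performance
demand
entire
rest
games
green
needs
race
seven
hair
technical
slightly
capital
sight
soon
met
structure
nor
condition
continue
treatment
role
aid
kept
pattern
moral
radio
phone
success
clearly
hospital
view
date
nearly
understanding
involved
baseball
filled
sun
relations
computer
meant
closed
village
alive
trip
southern
middle
christian
industrial
specific
temperature
degree
heavy
drive
former
added
article
spent
described
changed
inside
bottom
club
bed
thirty
dead
sign
window
shoulder
cat
dog
sea
sky
eat
ate
sit
map
cup
pen
box
kid
job
fun
bus
egg
leg
ear
eye
toe
hat
bag
bat
ball
tree
fish
bird
horse
cow
pig
sheep
goat
duck
hen
rain
snow
wind
storm
cloud
lake
hill
mountain
forest
grass
flower
leaf
root
stone
rock
sand
beach
ocean
ship
boat
train
truck
wheel
engine
roof
chair
desk
lamp
clock
watch
shirt
shoes
dress
coat
glass
plate
spoon
fork
knife
bread
milk
cheese
butter
sugar
salt
meat
rice
soup
cake
tea
coffee
fruit
apple
orange
banana
grape
lemon
potato
tomato
onion
bean
corn
wheat
garden
park
town
bridge
tower
castle
palace
temple
shop
store
gold
silver
iron
wood
cotton
silk
wool
team
game
score
goal
match
winner
loser
player
coach
rule
fair
luck
skill
brain
bone
skin
breath
sleep
dream
wake
walk
jump
climb
swim
dance
sing
laugh
cry
smile
shout
whisper
listen
touch
taste
smell
feel
carry
lift
push
pull
throw
catch
drop
pick
lock
unlock
begin
finish
start
wait
stay
arrive
depart
travel
journey
guest
host
enemy
neighbor
stranger
parent
child
baby
brother
sister
uncle
aunt
cousin
grandmother
grandfather
wedding
birthday
holiday
festival
gift
card
message
email
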