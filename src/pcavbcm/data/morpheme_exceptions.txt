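# Words that superficially end in an inflectional suffix but are monomorphemic
# (or otherwise not decomposed by the connected-speech coding rules).
# One word per line; '#' starts a comment.
is
his
this
its
was
has
does
goes
yes
as
us
thus
always
perhaps
besides
upstairs
downstairs
glass
grass
dress
mess
less
miss
kiss
across
dishes
maybe
the
she
he
during
thing
something
anything
nothing
everything
king
ring
spring
string
ceiling
morning
evening
darling
bring
sing
wing
red
bed
bread
head
instead
need
indeed
good
food
wood
bird
word
hundred
and
hand
stand
ground
around
kid
did
had
said
old
cold
child
would
could
should
her
other
another
mother
father
brother
sister
water
over
under
after
never
ever
either
neither
weather
together
remember
counter
dinner
summer
winter
butter
saucer
river
paper
flower
number
rather
wonder
corner
finger
upper
super
best
rest
west
east
nest
chest
just
must
first
last
most
almost
past
against
interest
breakfast
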