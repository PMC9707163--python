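%
1	i
2	we
3	you
4	shehe
5	they
6	ppron
7	pronoun
8	ipron
9	article
10	prep
11	auxverb
12	adverb
13	conj
14	negate
15	quant
16	number
17	interrog
18	compare
19	focuspast
20	focuspresent
21	focusfuture
22	certain
23	tentat
24	discrep
25	modal
26	causal
27	insight
28	differ
29	assent
30	nonflu
31	filler
32	swear
33	netspeak
34	intensifier
35	hedge
36	politeness
37	greeting
38	subordconj
39	relpron
%
i	1 6 7
me	1 6 7
my	1 6 7
mine	1 6 7
myself	1 6 7
i'm	1 6 7 20
i've	1 6 7
i'll	1 6 7 21
i'd	1 6 7
we	2 6 7
us	2 6 7
our	2 6 7
ours	2 6 7
ourselves	2 6 7
we're	2 6 7 20
we've	2 6 7
we'll	2 6 7 21
let's	2 6 7
you	3 6 7
your	3 6 7
yours	3 6 7
yourself	3 6 7
yourselves	3 6 7
you're	3 6 7 20
you've	3 6 7
you'll	3 6 7 21
you'd	3 6 7
she	4 6 7
he	4 6 7
her	4 6 7
him	4 6 7
his	4 6 7
hers	4 6 7
herself	4 6 7
himself	4 6 7
she's	4 6 7 20
he's	4 6 7 20
she'll	4 6 7 21
he'll	4 6 7 21
they	5 6 7
them	5 6 7
their	5 6 7
theirs	5 6 7
themselves	5 6 7
they're	5 6 7 20
they've	5 6 7
they'll	5 6 7 21
it	8 7
its	8 7
it's	8 7 20
this	8 7
that	8 7 39
these	8 7
those	8 7
something	8 7
anything	8 7
nothing	8 7 14
everything	8 7
thing	8 7
things	8 7
what	8 7 17
which	8 7 17 39
whatever	8 7
somebody	8 7
anybody	8 7
nobody	8 7 14
everybody	8 7
someone	8 7
anyone	8 7
everyone	8 7
a	9
an	9
the	9
in	10
on	10
at	10
of	10
to	10
for	10
with	10
from	10
about	10
into	10
over	10
under	10
between	10
through	10
during	10
before	10 19
after	10 19
above	10
below	10
against	10
among	10
within	10
without	10
across	10
behind	10
beyond	10
near	10
upon	10
off	10
up	10
down	10
around	10
out	10
am	11 20
is	11 20
are	11 20
was	11 19
were	11 19
be	11
been	11 19
being	11 20
have	11 20
has	11 20
had	11 19
having	11 20
do	11 20
does	11 20
did	11 19
doing	11 20
don't	11 14 20
doesn't	11 14 20
didn't	11 14 19
isn't	11 14 20
aren't	11 14 20
wasn't	11 14 19
weren't	11 14 19
haven't	11 14 20
hasn't	11 14 20
hadn't	11 14 19
very	12 34
really	12 34
just	12
quite	12 35
rather	12 24
too	12
also	12
again	12
almost	12 35
always	12 22
never	12 14 22
often	12
sometimes	12
usually	12
soon	12 21
already	12 19
still	12
yet	12
even	12
maybe	12 23
perhaps	12 23
here	12
there	12
now	12 20
then	12 19
well	12 30
away	12
back	12
together	12
and	13
but	13 28
or	13
nor	13 14
so	13 34
because	13 26 38
although	13 28 38
though	13 28 38
while	13 38
whereas	13 28 38
unless	13 38
until	13 38
since	13 26 38
if	13 38
when	13 17 38
whenever	13 38
as	13
than	13 18
no	14
not	14
none	14
neither	14
can't	14 25
cannot	14 25
won't	14 21 25
wouldn't	14 24 25
shouldn't	14 24 25
couldn't	14 24 25
all	15
some	15
many	15
much	15
few	15
several	15
most	15 18
more	15 18
less	15 18
least	15 18
lots	15
plenty	15
enough	15
every	15
each	15
any	15
both	15
half	15 16
whole	15
one	16
two	16
three	16
four	16
five	16
six	16
seven	16
eight	16
nine	16
ten	16
hundred	16
thousand	16
million	16
first	16
second	16
third	16
once	16
twice	16
who	17 39
whom	17 39
whose	17 39
where	17
why	17
how	17
better	18
worse	18
best	18
worst	18
bigger	18
smaller	18
greater	18
same	18
different	18 28
similar	18
ago	19
yesterday	19
earlier	19
went	19
said	19
told	19
saw	19
came	19
got	19
made	19
took	19
thought	19 27
knew	19 27
felt	19 27
today	20
currently	20
happening	20
will	21 25
gonna	21
shall	21 25
tomorrow	21
definitely	22
certainly	22
absolutely	22 29
sure	22 29
surely	22
clearly	22
obviously	22
totally	22 34
completely	22 34
truly	22
undoubtedly	22
possibly	23
probably	23
might	23 25
may	23 25
seem	23
seems	23
seemed	23 19
appear	23
appears	23
guess	23 27
somewhat	23 35
hopefully	23
likely	23
unsure	23
should	24 25
would	24 25
could	24 25
ought	24 25
hope	24
hopes	24
hoped	24 19
wish	24
wishes	24
wanted	24 19
want	24
wants	24
need	24
needs	24
needed	24 19
instead	24 28
expect	24
expected	24 19
must	25
can	25
cause	26
causes	26
caused	26 19
hence	26
therefore	26
thus	26
consequently	26
effect	26
effects	26
result	26
results	26
think	27 20
thinks	27 20
thinking	27 20
know	27 20
knows	27 20
knowing	27 20
consider	27
understand	27
understands	27
realize	27
realized	27 19
believe	27
believes	27
believed	27 19
feel	27 20
feels	27 20
feeling	27 20
mean	27
means	27
meant	27 19
except	28
however	28
otherwise	28
versus	28
unlike	28
yes	29
yeah	29
yep	29
okay	29
ok	29 33
agree	29
agreed	29 19
alright	29
fine	29
indeed	29
um	30
uh	30
er	30
hmm	30
oh	30
huh	30
ah	30
uhh	30
umm	30
blah	31
basically	31 12
literally	31 12
actually	31 12
honestly	31 12
anyway	31 12
damn	32
hell	32
crap	32
shit	32
shitty	32
fuck	32
fucking	32
fucked	32
ass	32
bitch	32
bastard	32
piss	32
pissed	32
lol	33
lmao	33
omg	33
btw	33
imo	33
imho	33
tbh	33
idk	33
wtf	33 32
thx	33
plz	33
u	33
ur	33
brb	33
smh	33
extremely	34 12
incredibly	34 12
super	34
highly	34 12
deeply	34 12
strongly	34 12
utterly	34 12
fairly	35 12
pretty	35
slightly	35 12
roughly	35 12
approximately	35 12
nearly	35 12
please	36
thanks	36
thank	36
sorry	36
welcome	36
excuse	36
pardon	36
appreciate	36
appreciated	36 19
hi	37
hello	37
hey	37
goodbye	37
bye	37
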