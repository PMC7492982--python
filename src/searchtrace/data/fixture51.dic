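%
1	funct
2	pronoun
3	ppron
4	i
5	we
6	you
7	shehe
8	they
9	ipron
10	article
11	verb
12	auxverb
13	past
14	present
15	future
16	adverb
17	preps
18	conj
19	negate
20	quant
21	number
22	swear
23	social
24	family
25	friend
26	humans
27	affect
28	posemo
29	negemo
30	anx
31	anger
32	sad
33	cogmech
34	insight
35	cause
36	discrep
37	tentat
38	certain
39	inhib
40	incl
41	excl
42	percept
43	see
44	hear
45	feel
46	bio
47	body
48	health
49	sexual
50	ingest
51	relativ
%
the	1	10
a	1	10
an	1	10
to	1	17
of	1	17
in	1	17
on	1	17
for	1	17
with	1	17	33	40
from	1	17
at	1	17
by	1	17
about	1	17
over	1	17	51
under	1	17	51
near	1	17	51
during	1	17	51
until	1	17	51
and	1	18	33	40
but	1	18	33	41
or	1	18	33	41
because	1	18	33	35
so	1	18
if	1	18
then	1	18	51
also	1	18
i	1	2	3	4
me	1	2	3	4
my	1	2	3	4
mine	1	2	3	4
myself	1	2	3	4
we	1	2	3	5
us	1	2	3	5
our	1	2	3	5
you	1	2	3	6
your	1	2	3	6
he	1	2	3	7
she	1	2	3	7
him	1	2	3	7
her	1	2	3	7
his	1	2	3	7
they	1	2	3	8
them	1	2	3	8
their	1	2	3	8
it	1	2	9
that	1	2	9
this	1	2	9
those	1	2	9
these	1	2	9
something	1	2	9
anything	1	2	9
someone	1	2	9	23
anyone	1	2	9	23
what	1	2	9
which	1	2	9
whatever	1	2	9
go	11	14
make	11
get	11
take	11
find	11
want	11	14
need	11	14
search	11
buy	11
watch	11	42	43
is	1	11	12	14
are	1	11	12	14
was	1	11	12	13
were	1	11	12	13
be	1	11	12
been	1	11	12	13
am	1	11	12	14
have	1	11	12	14
has	1	11	12	14
had	1	11	12	13
do	1	11	12	14
does	1	11	12	14
did	1	11	12	13
will	1	11	12	15
went	11	13
said	11	13	23
made	11	13
got	11	13
took	11	13
happened	11	13
gonna	1	11	12	15
shall	1	11	12	15
tomorrow	15	51
very	1	16
really	1	16
just	1	16
now	1	16	51
soon	1	16	51
quickly	1	16
always	1	16	33	38
never	1	16	19	33	38
no	1	19
not	1	19
none	1	19
cannot	1	19
don't	1	19
won't	1	19
isn't	1	19
without	1	17	33	41
few	1	20
many	1	20
much	1	20
more	1	20
most	1	20
some	1	20
all	1	20
lot	20
lots	20
several	1	20
little	1	20
one	21
two	21
three	21
first	21	51
second	21	51
ten	21
damn	22	27	29
hell	22	27	29
crap	22	27	29
shit	22	27	29
talk	23
call	23
text	23
chat	23
party	23
meet	23
social	23
people	23	26
person	23	26
human	23	26
man	23	26
woman	23	26
kids	23	26
mom	23	24
dad	23	24
mother	23	24
father	23	24
sister	23	24
brother	23	24
parents	23	24
friend	23	25
friends	23	25
buddy	23	25
pal	23	25
happy	27	28
good	27	28
love	27	28
nice	27	28
great	27	28
fun	27	28
hope	27	28
joy	27	28
glad	27	28
awesome	27	28
excited	27	28
beautiful	27	28
happ*	27	28
bad	27	29
hate	27	29	31
awful	27	29
terrible	27	29
ugly	27	29
worthless	27	29
nervous	27	29	30
anxious	27	29	30
anxiety	27	29	30
worried	27	29	30
worry	27	29	30
afraid	27	29	30
scared	27	29	30
tense	27	29	30
panic	27	29	30
stress	27	29	30
stressed	27	29	30
fear	27	29	30
worr*	27	29	30
angry	27	29	31
anger	27	29	31
mad	27	29	31
furious	27	29	31
rage	27	29	31
annoyed	27	29	31
pissed	22	27	29	31
hostile	27	29	31
fight	27	29	31
yell	27	29	31
kill	27	29	31
sad	27	29	32
sadness	27	29	32
cry	27	29	32
crying	27	29	32
grief	27	29	32
depressed	27	29	32
lonely	27	29	32
hopeless	27	29	32
miserable	27	29	32
tears	27	29	32
depress*	27	29	32
think	11	14	33	34
thought	33	34
know	11	14	33	34
believe	33	34
understand	33	34
realize	33	34
meaning	33	34
aware	33	34
reason	33	34	35
learn	33	34
consider	33	34
cause	33	35
effect	33	35
why	33	35
how	33	35
result	33	35
should	1	11	12	33	36
would	1	11	12	33	36
could	1	11	12	33	36
wish	33	36
ought	33	36
maybe	33	37
perhaps	33	37
guess	33	37
possibly	33	37
seem	33	37
seems	33	37
sure	33	38
certain	33	38
definitely	33	38
totally	33	38
exact	33	38
block	33	39
stop	33	39
control	33	39
restrain	33	39
constrain	33	39
limit	33	39
avoid	33	39
prevent	33	39
forbid	33	39
ban	33	39
hold	33	39
contain	33	39
include	33	40
included	33	40
including	33	40
both	33	40
together	33	40
plus	33	40
add	33	40
along	33	40
inside	33	40	51
open	33	40
except	33	41
exclude	33	41
either	33	41
sense	42
observe	42	43
perception	42
see	42	43
saw	42	43
seen	42	43
look	42	43
looking	42	43
view	42	43
eyes	42	43	47
hear	42	44
heard	42	44
hearing	42	44
listen	42	44
listening	42	44
sound	42	44
sounds	42	44
voice	42	44
voices	42	44
music	42	44
loud	42	44
noise	42	44
feel	42	45
feels	42	45
felt	42	45
feeling	42	45
touch	42	45
soft	42	45
body	46	47
head	46	47
hair	46	47
skin	46	47
hands	46	47
face	46	47
stomach	46	47
heart	46	47
blood	46	47
health	46	48
doctor	46	48
medicine	46	48
pill	46	48
pills	46	48
sick	46	48
hospital	46	48
clinic	46	48
symptom	46	48
symptoms	46	48
pain	46	47	48
flu	46	48
therapy	46	48
medication	46	48
ill*	46	48
sex	46	49
sexual	46	49
sexy	46	49
porn	46	49
naked	46	49
horny	46	49
kiss	23	46	49
gay	46	49
lust	46	49
dating	23	46	49
eat	46	50
eating	46	50
food	46	50
drink	46	50
dinner	46	50
lunch	46	50
pizza	46	50
hungry	46	50
time	51
today	51
here	51
there	51
when	51
where	51
far	51
move	51
fast	51
slow	51
up	51
down	51
new	51
old	51
night	51
morning	51
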