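%
1	insight
2	causation
3	discrepancy
4	tentativeness
5	certitude
6	differentiation
7	memory
8	need
9	want
10	lack
11	reward
12	risk
13	curiosity
14	substances
15	food
16	death
17	interpersonal_conflict
18	communication
19	negative_tone
20	anxiety
21	anger
22	sadness
23	swear_words
%
think*	1
know	1
knew	1
realiz*	1
understand*	1
understood	1
insight*	1
reflect*	1
reason*	1
aware*	1
notice*	1
recogni*	1
consider*	1
perceive*	1
interpret*	1
because	2
cause*	2
caus*	2
effect*	2
hence	2
therefore	2
since	2
result*	2
depend*	2
influenc*	2
due	2
consequen*	2
outcome*	2
trigger*	2
should	3
would	3
could	3
ought	3
hope*	3
expect*	3
prefer*	3
ideal*	3
if	3
supposed	3
rather	3
instead	3
maybe	4
perhaps	4
guess*	4
seem*	4
possib*	4
somewhat	4
sort	4
kinda	4
unsure	4
tentativ*	4
unclear	4
vague*	4
apparent*	4
always	5
definitely	5
certain*	5
absolutely	5
surely	5
clearly	5
obvious*	5
undoubted*	5
exact*	5
truly	5
completely	5
but	6
except	6
however	6
although	6
though	6
whereas	6
distinct*	6
differ*	6
unlike	6
contrast*	6
versus	6
otherwise	6
remember*	7
forget*	7
forgot*	7
recall*	7
memor*	7
remind*	7
nostalg*	7
flashback*	7
reminisc*	7
need*	8
necessit*	8
essential*	8
must	8
require*	8
vital	8
necessary	8
want*	9
desire*	9
crave*	9
wish*	9
yearn*	9
eager*	9
keen	9
lack*	10
without	10
miss*	10
absent*	10
shortage*	10
insufficien*	10
deficit*	10
deprive*	10
scarce*	10
reward*	11
prize*	11
bonus*	11
achiev*	11
trophy	11
win	11
won	11
earn*	11
medal*	11
incentive*	11
accomplish*	11
risk*	12
danger*	12
unsafe	12
hazard*	12
threat*	12
caution*	12
warn*	12
peril*	12
reckless*	12
curio*	13
wonder*	13
explor*	13
question*	13
investigat*	13
search*	13
discover*	13
intrigu*	13
inquir*	13
fascinat*	13
alcohol*	14
beer	14
wine	14
drunk	14
cigarette*	14
tobacco	14
vape*	14
drug*	14
weed	14
cocaine	14
pill*	14
sober	14
food*	15
eat*	15
ate	15
hungry	15
meal*	15
snack*	15
dinner	15
lunch	15
breakfast	15
cook*	15
pizza	15
sandwich*	15
dessert*	15
death*	16
dead	16
die*	16
dying	16
funeral*	16
grave*	16
bury*	16
buried	16
coffin*	16
fatal*	16
deceased	16
argu*	17
fight*	17
fought	17
conflict*	17
quarrel*	17
dispute*	17
blame*	17
insult*	17
hostil*	17
feud*	17
clash*	17
betray*	17
talk*	18
chat*	18
tell*	18
told	18
discuss*	18
convers*	18
messag*	18
email*	18
phone*	18
speak*	18
spoke	18
announc*	18
bad	19
awful	19
terrible	19
horrible	19
nasty	19
ugly	19
worse	19
worst	19
gross	19
unpleasant*	19
negativ*	19
dreadful	19
nervous*	20
panic*	20
afraid	20
fear*	20
scared	20
tense	20
uneasy	20
dread	20
apprehensiv*	20
jitter*	20
fright*	20
phobi*	20
angry	21
anger*	21
mad	21
furious	21
rage*	21
annoy*	21
irritat*	21
outrag*	21
resent*	21
hate*	21
hated	21
grief*	22
unhappy	22
miserable	22
gloomy	22
depress*	22
mourn*	22
sorrow*	22
tear*	22
lonely	22
hopeless*	22
weep*	22
heartbroken	22
damn*	23
hell	23
crap*	23
shit*	23
fuck*	23
bitch*	23
bastard*	23
asshole*	23
piss*	23
bloody	23
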