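%
1	achievement
2	benevolence
3	conformity
4	hedonism
5	power
6	security
7	self-direction
8	stimulation
9	tradition
10	universalism
%
achiev*	1
success*	1
succeed*	1
accomplish*	1
ambiti*	1
goal*	1
win*	1
excel*	1
effort*	1
competen*	1
master*	1
help*	2
kind*	2
caring	2
care*	2
support*	2
friend*	2
loyal*	2
generous*	2
forgiv*	2
comfort*	2
compassion*	2
obey*	3
obedien*	3
rule*	3
norm*	3
polite*	3
proper*	3
disciplin*	3
comply*	3
conform*	3
respect*	3
fun	4
enjoy*	4
pleasur*	4
delight*	4
party*	4
tasty	4
relax*	4
entertain*	4
indulg*	4
joy*	4
power*	5
control*	5
dominat*	5
status	5
wealth*	5
authorit*	5
influen*	5
prestig*	5
command*	5
rich*	5
safe*	6
secur*	6
protect*	6
stable	6
stabilit*	6
health*	6
order*	6
clean*	6
insur*	6
guard*	6
freedom*	7
independen*	7
choos*	7
choice*	7
creat*	7
curious*	7
curiosit*	7
explor*	7
autonom*	7
original*	7
excit*	8
adventur*	8
thrill*	8
novel*	8
daring	8
risk*	8
stimulat*	8
bold*	8
variety*	8
tradition*	9
custom*	9
heritag*	9
ritual*	9
religio*	9
humble*	9
modest*	9
devout*	9
ancestor*	9
faith*	9
equal*	10
justice*	10
peace*	10
environment*	10
nature*	10
tolera*	10
unity*	10
world*	10
fairness*	10
harmony*	10
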