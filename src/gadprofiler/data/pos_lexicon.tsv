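dogs	NOUN
dog	NOUN
cat	NOUN
cats	NOUN
worry	VERB
worries	NOUN
worrying	VERB
worried	VERB
anxiety	NOUN
anxious	ADJ
sleep	VERB
slept	VERB
sleeping	VERB
feel	VERB
felt	VERB
feeling	NOUN
feelings	NOUN
think	VERB
thought	NOUN
thinking	VERB
know	VERB
knew	VERB
run	VERB
ran	VERB
running	VERB
go	VERB
went	VERB
going	VERB
say	VERB
said	VERB
make	VERB
made	VERB
get	VERB
got	VERB
take	VERB
took	VERB
see	VERB
saw	VERB
work	VERB
worked	VERB
working	VERB
cry	VERB
cried	VERB
crying	VERB
help	VERB
helped	VERB
need	VERB
needed	VERB
want	VERB
wanted	VERB
good	ADJ
bad	ADJ
happy	ADJ
sad	ADJ
tired	ADJ
scared	ADJ
nervous	ADJ
never	ADV
always	ADV
often	ADV
today	NOUN
tomorrow	NOUN
yesterday	NOUN
exam	NOUN
exams	NOUN
school	NOUN
job	NOUN
jobs	NOUN
friend	NOUN
friends	NOUN
family	NOUN
health	NOUN
doctor	NOUN
night	NOUN
day	NOUN
days	NOUN
time	NOUN
life	NOUN
people	NOUN
heart	NOUN
mind	NOUN
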