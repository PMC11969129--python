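worrying	VERB	worry
worried	VERB	worry
worries	NOUN	worry
worries	VERB	worry
running	VERB	run
ran	VERB	run
runs	VERB	run
exams	NOUN	exam
dogs	NOUN	dog
cats	NOUN	cat
feelings	NOUN	feeling
felt	VERB	feel
thinking	VERB	think
thought	VERB	think
thoughts	NOUN	thought
knew	VERB	know
knows	VERB	know
went	VERB	go
going	VERB	go
goes	VERB	go
said	VERB	say
says	VERB	say
made	VERB	make
makes	VERB	make
got	VERB	get
gets	VERB	get
took	VERB	take
takes	VERB	take
saw	VERB	see
sees	VERB	see
worked	VERB	work
working	VERB	work
works	VERB	work
cried	VERB	cry
crying	VERB	cry
cries	VERB	cry
helped	VERB	help
helps	VERB	help
needed	VERB	need
needs	VERB	need
wanted	VERB	want
wants	VERB	want
slept	VERB	sleep
sleeping	VERB	sleep
sleeps	VERB	sleep
jobs	NOUN	job
friends	NOUN	friend
families	NOUN	family
doctors	NOUN	doctor
nights	NOUN	night
days	NOUN	day
times	NOUN	time
lives	NOUN	life
hearts	NOUN	heart
minds	NOUN	mind
kids	NOUN	kid
parents	NOUN	parent
partners	NOUN	partner
emotions	NOUN	emotion
symptoms	NOUN	symptom
muscles	NOUN	muscle
treatments	NOUN	treatment
schools	NOUN	school
colleges	NOUN	college
offices	NOUN	office
salaries	NOUN	salary
promotions	NOUN	promotion
experiences	NOUN	experience
businesses	NOUN	business
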