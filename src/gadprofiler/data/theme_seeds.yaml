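# Default guided-topic seed words, one list per theme.
# Symptoms seeds follow DSM-5 GAD symptomatology; the other themes cover the
# life domains the disorder is known to impair.
symptoms:
  - worry
  - concern
  - anxiety
  - twitch
  - treatment
  - restlessness
  - concentration
  - muscle
  - mental
  - health
life_problems:
  - business
  - money
  - work
  - school
  - job
  - salary
  - promotion
  - college
  - office
  - experience
relationships:
  - wife
  - husband
  - parents
  - kids
  - friends
  - partners
  - spouse
  - fiancee
  - fiance
  - father
feelings:
  - feel
  - cry
  - respect
  - release
  - support
  - emotion
  - disclosure
  - care
  - sadness
  - sense
  - sorry
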