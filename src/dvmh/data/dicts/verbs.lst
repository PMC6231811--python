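# Verbs in common lexical patterns indicating a mental health disorder.
suffer
suffers
suffering
suffered
takes
taking
taken
took
uses
using
used
struggles
struggling
struggled
battles
battling
battled
experiences
experiencing
experienced
abuses
abusing
abused
diagnosed
addicted
treated
medicated
admits
admitted
appears
appeared
exhibits
exhibited
displays
displayed
displaying
shows
showing
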