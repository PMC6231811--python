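# Conjugations of "have" in present and past tense (incl. compound forms).
has
have
had
having
has been
have been
had been
has had
have had
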