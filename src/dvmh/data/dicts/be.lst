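# Conjugations of "be" in present and past tense.
is
are
was
were
being
been
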