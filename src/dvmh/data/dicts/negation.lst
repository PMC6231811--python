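# Terms indicating negated context.
not
no
none
never
denies
denied
denying
doesn't
don't
didn't
isn't
wasn't
aren't
weren't
hasn't
haven't
hadn't
cannot
can't
won't
without
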