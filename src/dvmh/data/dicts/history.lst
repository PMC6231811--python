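# Variations of mental-health history mentions.
a history of
history of
a long history of
a short history of
a serious history of
serious history of
an extensive history of
extensive history of
a past history of
past history of
a known history of
known history of
a medical history of
hx of
a hx of
h/o
extensive h/o
a h/o
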