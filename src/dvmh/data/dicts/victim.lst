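# Terms describing a victim in a DV event.
victim
victims
vic
vics
pn
pinop
complainant
aggrieved
person in need of protection
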