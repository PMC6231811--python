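# Illegal drugs known to cause addiction.
cannabis	Cannabis abuse
marijuana	Cannabis abuse
heroin	Opioid abuse
opioids	Opioid abuse
opiates	Opioid abuse
methadone	Opioid abuse
methamphetamine	Stimulant abuse
methamphetamines	Stimulant abuse
meth	Stimulant abuse
amphetamine	Stimulant abuse
amphetamines	Stimulant abuse
ice	Stimulant abuse
speed	Stimulant abuse
cocaine	Cocaine abuse
crack	Cocaine abuse
ecstasy	Other psychoactive substance abuse
mdma	Other psychoactive substance abuse
lsd	Other psychoactive substance abuse
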