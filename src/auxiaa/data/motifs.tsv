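# Aux/IAA conserved motif blocks as degenerate amino-acid patterns.
# I  = N-terminal leucine-repeat repressor motif; II = TIR1/AFB degron core;
# III/IV = dimerization blocks.  III/IV consensus strings are package
# conventions (no community consensus string exists); all are configurable.
I	LxLxLx
II	GWPP[VI]
III	VKV[SN]MDGAPYLRK
IV	GDVPWEMF[VI]
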