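name	class	triad	motif	diagnostics
PpASCL_syn	ASCL	170:C,305:H,338:N	[AG]FGPG	225:G:ASCL;240:[AV]:ASCL
PpORS_syn	ORS	170:C,305:H,338:N	[AG]FGPG	218:Q:ORS;277:[AV]:ORS;286:A:ORS
PKSIII_generic_syn	other_PKSIII	170:C,305:H,338:N	[AG]FGPG	
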