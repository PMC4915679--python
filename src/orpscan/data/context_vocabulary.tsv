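category	keyword
transducer	methyl-accepting chemotaxis
transducer	HAMP
transducer	signal transducer
transducer	MCP
taxis_operon	CheW
taxis_operon	CheA
taxis_operon	CheB
taxis_operon	CheY
taxis_operon	flagellin
taxis_operon	flagellar
taxis_operon	fla operon
taxis_operon	chemotaxis protein
stress	heat shock
stress	chaperone
stress	carbon starvation
stress	metal
stress	universal stress
stress	cold shock
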