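pair	AU	UA	GC	CG	GU	UG
AU	-0.9	-1.1	-2.1	-2.2	-0.6	-1.4
UA	-1.3	-0.9	-2.4	-2.1	-1.0	-1.3
GC	-2.1	-2.2	-3.3	-3.4	-1.4	-2.5
CG	-2.4	-2.1	-3.0	-3.3	-1.5	-2.1
GU	-1.3	-1.4	-2.5	-2.1	-0.5	-0.4
UG	-1.0	-0.6	-1.5	-1.4	-0.2	-0.4
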