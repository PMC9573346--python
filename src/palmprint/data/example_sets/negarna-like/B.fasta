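>negarna-like|B|seed01
QGILEYTSSFVHEM
>negarna-like|B|seed02
QGAGDYTVSLLHEM
>negarna-like|B|seed03
QGILHNTSSLLIEM
>negarna-like|B|seed04
GGDVHYVSSLLHEK
>negarna-like|B|seed05
QGGQHYTSSLLHEH
>negarna-like|B|seed06
QGILHYTSSALHEM
>negarna-like|B|seed07
QGILQYTGSLLHEM
>negarna-like|B|seed08
QGILHYTSSLLHEM
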