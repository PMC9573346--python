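>pisuvi-like|C|seed01
SDYGDDLIVSVRA
>pisuvi-like|C|seed02
SQYGDDLIVSVGF
>pisuvi-like|C|seed03
SQYGDDLIQSVRA
>pisuvi-like|C|seed04
SQYGDDLIVSVRA
>pisuvi-like|C|seed05
SQYGDDLIVGVRA
>pisuvi-like|C|seed06
SQYGDDLIVSGRT
>pisuvi-like|C|seed07
SQYGDDLIVLVRA
>pisuvi-like|C|seed08
SQYGDDLIVSVRA
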