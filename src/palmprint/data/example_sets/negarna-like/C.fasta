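>negarna-like|C|seed01
FSWGDDGLSCLEH
>negarna-like|C|seed02
FSWGDDGLSTLEH
>negarna-like|C|seed03
LIWGDDFESTVEH
>negarna-like|C|seed04
FSWGDDGLSTLSH
>negarna-like|C|seed05
FSWGDDGLSTLEH
>negarna-like|C|seed06
FSIGDDGHDTDEH
>negarna-like|C|seed07
FSRGDDGLSTLEH
>negarna-like|C|seed08
FSWGDDGLSTSEH
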