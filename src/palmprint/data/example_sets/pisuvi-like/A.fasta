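>pisuvi-like|A|seed01
DYSFFDGLSSWV
>pisuvi-like|A|seed02
DYSQFDGGSSRV
>pisuvi-like|A|seed03
DYSQFDGLSSGV
>pisuvi-like|A|seed04
DYSQFDILGSRV
>pisuvi-like|A|seed05
DYSQSDGLSSRV
>pisuvi-like|A|seed06
DYSQFDGLSSRV
>pisuvi-like|A|seed07
DYSAFDGLSSRV
>pisuvi-like|A|seed08
DYSQFDGLSSRV
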