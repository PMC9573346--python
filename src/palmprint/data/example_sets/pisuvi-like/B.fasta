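>pisuvi-like|B|seed01
IGNPGTSLKNTILN
>pisuvi-like|B|seed02
SGEIGTSLIITILN
>pisuvi-like|B|seed03
HGNPGTSLINTHLT
>pisuvi-like|B|seed04
SGNLGTSHINTILN
>pisuvi-like|B|seed05
FGNPGTSLILNILN
>pisuvi-like|B|seed06
SGNPGTSLINTILN
>pisuvi-like|B|seed07
SGNPGTSPIATILN
>pisuvi-like|B|seed08
SGNPGTSLINTILN
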