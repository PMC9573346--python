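>birna-permuted-like|C|seed01
WKAADNSPLDTFH
>birna-permuted-like|C|seed02
WKAADNSPLMTFH
>birna-permuted-like|C|seed03
WKAADNSPLDTFH
>birna-permuted-like|C|seed04
WKAADNSPLDTFH
>birna-permuted-like|C|seed05
WFAADNSPLARFG
>birna-permuted-like|C|seed06
WKAADNSPLDTFH
>birna-permuted-like|C|seed07
WKRADNSPLDTFH
>birna-permuted-like|C|seed08
WKAADNSPLDTLH
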