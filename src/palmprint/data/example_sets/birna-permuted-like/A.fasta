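>birna-permuted-like|A|seed01
DTTPGDWSEVLN
>birna-permuted-like|A|seed02
DFTAGDNSLVLN
>birna-permuted-like|A|seed03
DTTAGDNSEVLD
>birna-permuted-like|A|seed04
DFLAGDNSEKLN
>birna-permuted-like|A|seed05
DFTAGDNSYSCN
>birna-permuted-like|A|seed06
DSTAGDNSEHGN
>birna-permuted-like|A|seed07
DFTAGDKVEVLN
>birna-permuted-like|A|seed08
DFTAVDGSEVLN
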