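>birna-permuted-like|B|seed01
TGFGLGDFVTTLNR
>birna-permuted-like|B|seed02
TGLPSGDFVTQLWR
>birna-permuted-like|B|seed03
TGLPSGHFATQLWE
>birna-permuted-like|B|seed04
TGLPSGHPATQLVV
>birna-permuted-like|B|seed05
AGLPSGHFAAQLWR
>birna-permuted-like|B|seed06
TGLPSGHFFTALVY
>birna-permuted-like|B|seed07
TGMPSGHFATQLWR
>birna-permuted-like|B|seed08
TGLPSGHFGTQLWR
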