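>artverv-RT-like|B|seed01
KGISPGLWQYQWNV
>artverv-RT-like|B|seed02
KGISPGLWAQQWNV
>artverv-RT-like|B|seed03
KGISPGLWQYGFNV
>artverv-RT-like|B|seed04
KGIAPGLWQYQWNV
>artverv-RT-like|B|seed05
KGISPGLWQYQWNV
>artverv-RT-like|B|seed06
KGISPGLWQYQWNV
>artverv-RT-like|B|seed07
KGISPGLWTYQWNV
>artverv-RT-like|B|seed08
KGISPGLWQYQWNV
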