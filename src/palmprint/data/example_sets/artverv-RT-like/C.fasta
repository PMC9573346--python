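>artverv-RT-like|C|seed01
GIAQYMDDILIA
>artverv-RT-like|C|seed02
GIYQYMDDVLIA
>artverv-RT-like|C|seed03
GIQQNMDDALIA
>artverv-RT-like|C|seed04
GIYTSMDDILIA
>artverv-RT-like|C|seed05
FIYQYMDDILIA
>artverv-RT-like|C|seed06
GIYQYMDDILIA
>artverv-RT-like|C|seed07
GIYQYMDDILIA
>artverv-RT-like|C|seed08
GIYQYMDDILIG
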