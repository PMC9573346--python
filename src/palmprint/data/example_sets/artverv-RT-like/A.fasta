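>artverv-RT-like|A|seed01
DVKKADPQIQLH
>artverv-RT-like|A|seed02
DVKGADFEIKLH
>artverv-RT-like|A|seed03
DVKGCDPQCQLH
>artverv-RT-like|A|seed04
DVKGADPQIQLH
>artverv-RT-like|A|seed05
DVKGADPQIQQN
>artverv-RT-like|A|seed06
DVKRADPQIYLH
>artverv-RT-like|A|seed07
DVKGADPQITLH
>artverv-RT-like|A|seed08
DVKGADPQAQEH
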