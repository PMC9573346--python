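>negarna-like|A|seed01
DMSQFDTLGLHH
>negarna-like|A|seed02
DMSKFDTLGLHH
>negarna-like|A|seed03
DHSKFDTLGLHI
>negarna-like|A|seed04
DMGKFDTLGLHH
>negarna-like|A|seed05
DMSKFDTLGLHH
>negarna-like|A|seed06
DMSKFDTLGLHH
>negarna-like|A|seed07
DASKFDTLGLHH
>negarna-like|A|seed08
DMLKFDTLGLHH
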