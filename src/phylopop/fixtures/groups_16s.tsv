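EP	EP
GA	EP
MT	CP+WP
TPP	CP+WP
HC	CP+WP
IN	CP+WP
NC	CP+WP
FPP	CP+WP
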