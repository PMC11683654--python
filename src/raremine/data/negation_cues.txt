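no
not
without
denies
denied
absence of
absent
no evidence of
negative for
free of
lack of
lacks
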