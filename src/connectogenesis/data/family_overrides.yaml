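# Family-name overrides applied after suffix stripping: stems whose family
# cannot be decided by stripping trailing laterality/position letters alone.
URY: UR
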